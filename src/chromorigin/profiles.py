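"""Per-sample mutation profiles and the windows x chromatin-features matrix.

A :class:`MutationProfile` is the per-window somatic mutation count vector
of one sample (the regression target); a :class:`ChromatinMatrix` holds
per-window ChIP-seq read counts for many chromatin-mark features (the
predictors), with :class:`FeatureMetadata` mapping each feature to its
tissue/cell type and histone mark.  Both are aligned to the same
:class:`~chromorigin.windows.WindowSet` row axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import WindowSet

logger = logging.getLogger(__name__)

HISTONE_MARKS = (
    "H3K27me3",
    "H3K9me3",
    "H3K27ac",
    "H3K36me3",
    "H3K4me1",
    "H3K4me3",
    "H3K9ac",
)


@dataclass
class MutationProfile:
    """Per-window somatic mutation counts for one sample."""

    sample_id: str
    counts: np.ndarray
    window_fingerprint: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("negative mutation count")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass
class FeatureMetadata:
    """feature_id -> (tissue/cell type, histone mark, source)."""

    table: pd.DataFrame  # index: feature_id; columns: tissue_type, mark, source

    def __post_init__(self) -> None:
        required = {"tissue_type", "mark"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        if "source" not in self.table.columns:
            self.table = self.table.assign(source="")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature_id in metadata: {dups}")

    def tissue_of(self, feature_id: str) -> str:
        try:
            return str(self.table.loc[feature_id, "tissue_type"])
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in metadata") from None

    def tissues(self) -> list[str]:
        return sorted(self.table["tissue_type"].unique())

    @classmethod
    def from_tsv(cls, path) -> "FeatureMetadata":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "feature_id" not in df.columns:
            raise ValueError(f"{path}: metadata needs a feature_id column")
        return cls(df.set_index("feature_id"))

    def to_tsv(self, path) -> None:
        self.table.rename_axis("feature_id").reset_index().to_csv(
            path, sep="\t", index=False
        )


@dataclass
class ChromatinMatrix:
    """windows x features read-count matrix (rows = window indices)."""

    values: pd.DataFrame
    window_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("chromatin matrix contains missing cells")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("chromatin matrix contains negative counts")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate feature ids in matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def check_metadata(self, meta: FeatureMetadata) -> None:
        unknown = [f for f in self.feature_ids if f not in meta.table.index]
        if unknown:
            raise ValueError(f"features missing from metadata: {unknown[:5]}")

    @classmethod
    def from_tsv(cls, path) -> "ChromatinMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.values.rename_axis("window_index").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# counting


def count_mutations(variants, ws: WindowSet, sample_id: str) -> MutationProfile:
    """Tally variants (chrom, 1-based pos) into retained windows.

    Variants on unknown chromosomes or in non-retained regions are dropped;
    their number is logged and recorded on the returned profile.
    """
    if len(ws) == 0:
        raise ValueError("empty WindowSet")
    counts = np.zeros(len(ws), dtype=np.int64)
    dropped = 0
    for chrom, pos in variants:
        pos = int(pos)
        if pos <= 0:
            raise ValueError(f"non-positive variant position: {chrom}:{pos}")
        idx = ws.locate(str(chrom), pos - 1)
        if idx is None:
            dropped += 1
        else:
            counts[idx] += 1
    if dropped:
        logger.info("%s: %d variants outside retained windows", sample_id, dropped)
    return MutationProfile(sample_id, counts, ws.fingerprint(), n_dropped=dropped)


def count_feature_reads(intervals, ws: WindowSet) -> np.ndarray:
    """Tally reads/intervals (0-based half-open) by midpoint into windows."""
    counts = np.zeros(len(ws), dtype=np.int64)
    for chrom, start, end in intervals:
        start, end = int(start), int(end)
        if end <= start:
            raise ValueError(f"interval end <= start: {(chrom, start, end)}")
        idx = ws.locate(str(chrom), (start + end) // 2)
        if idx is not None:
            counts[idx] += 1
    return counts


def assemble_matrix(
    columns: dict[str, np.ndarray],
    meta: FeatureMetadata,
    ws: WindowSet,
    scale_columns: bool = False,
) -> ChromatinMatrix:
    """Column-sorted windows x features matrix from per-feature count vectors.

    ``scale_columns`` divides each column by its total (library-size scaling);
    off by default — tree models are insensitive to monotone per-column
    transforms.
    """
    if len(set(columns)) != len(columns):
        raise ValueError("duplicate feature_id")
    data = {}
    for fid in sorted(columns):
        vec = np.asarray(columns[fid])
        if vec.shape != (len(ws),):
            raise ValueError(
                f"feature {fid!r}: vector length {vec.shape} != {len(ws)} windows"
            )
        if fid not in meta.table.index:
            raise ValueError(f"feature {fid!r} not present in metadata")
        data[fid] = vec
    df = pd.DataFrame(data, index=pd.RangeIndex(len(ws), name="window_index"))
    if scale_columns:
        totals = df.sum(axis=0).replace(0, 1)
        df = df / totals
    return ChromatinMatrix(df, ws.fingerprint())


# ---------------------------------------------------------------------------
# profile arithmetic and sample selection


def aggregate_profiles(profiles: list[MutationProfile], group_id: str) -> MutationProfile:
    """Element-wise sum of aligned profiles (aggregate-sample analysis)."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.counts) != len(ref.counts) or p.window_fingerprint != ref.window_fingerprint:
            raise ValueError(
                f"profile {p.sample_id!r} built against a different WindowSet"
            )
    total = np.sum([p.counts for p in profiles], axis=0)
    return MutationProfile(group_id, total, ref.window_fingerprint)


def per_mb_density(p: MutationProfile) -> float:
    """Mean mutations per retained window (per-Mb density at 1 Mb windows)."""
    if len(p.counts) == 0:
        raise ValueError("profile over empty WindowSet")
    return p.n_total / len(p.counts)


def filter_by_density(
    profiles: list[MutationProfile],
    min_density: float = 0.0,
    max_density: float = float("inf"),
) -> list[MutationProfile]:
    """Keep profiles with min <= density <= max (hypermutator / clone selection)."""
    if min_density > max_density:
        raise ValueError("min_density > max_density")
    kept, excluded = [], []
    for p in profiles:
        (kept if min_density <= per_mb_density(p) <= max_density else excluded).append(p)
    if excluded:
        logger.info(
            "density filter excluded %d samples: %s",
            len(excluded),
            [p.sample_id for p in excluded],
        )
    return kept


def stratified_density_sample(
    profiles: list[MutationProfile],
    bin_width: float,
    n_per_bin: int,
    seed: int,
) -> list[MutationProfile]:
    """Draw up to ``n_per_bin`` profiles per density bin [k*w, (k+1)*w).

    Selection is without replacement within each bin, deterministic for a
    fixed seed; output preserves the input ordering of the selected profiles.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    rng = np.random.default_rng(seed)
    bins: dict[int, list[int]] = {}
    for i, p in enumerate(profiles):
        bins.setdefault(int(per_mb_density(p) // bin_width), []).append(i)
    chosen: list[int] = []
    for k in sorted(bins):
        members = bins[k]
        take = min(n_per_bin, len(members))
        chosen.extend(rng.choice(members, size=take, replace=False))
    return [profiles[i] for i in sorted(chosen)]


def write_profile(p: MutationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#sample_id={p.sample_id}\twindow_fingerprint={p.window_fingerprint}\n"
        )
        for i, c in enumerate(p.counts):
            fh.write(f"{i}\t{c}\n")


def read_profile(path) -> MutationProfile:
    sample_id, fingerprint = "", ""
    counts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    key, _, val = part.partition("=")
                    if key == "sample_id":
                        sample_id = val
                    elif key == "window_fingerprint":
                        fingerprint = val
                continue
            idx, count = line.split("\t")
            if int(idx) != len(counts):
                raise ValueError(f"{path}: line {lineno}: non-dense window index")
            counts.append(int(count))
    return MutationProfile(sample_id, np.asarray(counts), fingerprint)


def read_variants(path):
    """Yield (chrom, pos_1based) from a VCF or a headerless 2-column TSV."""
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        from cyvcf2 import VCF

        for rec in VCF(path):
            yield rec.CHROM, rec.POS
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                yield fields[0], int(fields[1])
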