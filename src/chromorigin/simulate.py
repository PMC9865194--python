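"""Synthetic windows, chromatin matrices and mutation profiles.

Generates the statistical structure the method assumes: each tissue has a
latent per-window chromatin profile; its ChIP-seq features are correlated
noisy negative-binomial renderings of that profile; one designated driver
tissue's profile drives a sample's regional mutation density through a
log-linear Poisson model.  Defaults emulate the published data regimes —
2128 retained 1-Mb windows, per-window mutation densities around 1 (the
normal-clone regime; stem cells sit near 0.1, tumours above 5), strong
within-tissue feature correlation, and a negative effect of the
active-chromatin signal on mutation density (mutation depletion in open
chromatin).  Every quantity is reproducible from ``SimConfig.seed``.

The generator does not emulate mutational signatures, replication-timing
gradients, or the spatial autocorrelation of real ChIP-seq tracks.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from ._seeds import derive_seed
from .profiles import (
    HISTONE_MARKS,
    ChromatinMatrix,
    FeatureMetadata,
    MutationProfile,
    assemble_matrix,
    count_mutations,
)
from .windows import ExclusionSet, WindowSet, build_windows, write_windows

import pandas as pd


@dataclass
class SimConfig:
    """Simulation conditions (defaults are the reference study conditions)."""

    n_windows: int = 2128
    n_tissues: int = 8
    features_per_tissue: int = 8
    within_tissue_correlation: float = 0.9  # rho
    driver_tissue: str = "tissue01"
    effect_size: float = -1.0  # b, on the standardized driver profile
    baseline_density: float = 1.0  # mean mutations per window
    dispersion: float = 10.0  # NB size for feature read counts
    noise_sd: float = 0.3  # extra log-normal noise on the mutation mean
    feature_mean_reads: float = 500.0  # mean ChIP-seq reads per window
    chromatin_log_sd: float = 0.5  # log-scale spread of read intensity
    n_chromosomes: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.within_tissue_correlation < 1.0):
            raise ValueError("within_tissue_correlation must be in [0, 1)")
        for name in ("n_windows", "n_tissues", "features_per_tissue",
                     "baseline_density", "dispersion", "feature_mean_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    driver_tissue: str
    driver_feature_ids: list[str]
    driver_signal: np.ndarray  # standardized latent profile, length n_windows
    latents: dict = field(default_factory=dict, repr=False)


def simulate_chromatin(config: SimConfig):
    """Simulate the windows x features matrix with planted tissue structure.

    Per tissue, a standard-normal latent profile over windows; feature k of
    tissue t is sqrt(rho) * latent_t + sqrt(1-rho) * private noise, mapped
    to negative-binomial read counts through a log link.
    """
    tissues = config.tissue_names()
    if config.driver_tissue not in tissues:
        raise ValueError(f"driver_tissue {config.driver_tissue!r} not among tissues")
    rng = np.random.default_rng(derive_seed(config.seed, "chromatin"))
    rho = config.within_tissue_correlation
    n = config.n_windows
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    latents: dict[str, np.ndarray] = {}
    for t_i, tissue in enumerate(tissues):
        latent = rng.standard_normal(n)
        latents[tissue] = latent
        for k in range(config.features_per_tissue):
            fid = f"{tissue}_{HISTONE_MARKS[k % len(HISTONE_MARKS)]}_{k:02d}"
            z = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.standard_normal(n)
            mean = config.feature_mean_reads * np.exp(
                config.chromatin_log_sd * z - config.chromatin_log_sd**2 / 2
            )
            size = config.dispersion
            counts = rng.negative_binomial(size, size / (size + mean))
            columns[fid] = counts
            meta_rows.append(
                {
                    "feature_id": fid,
                    "tissue_type": tissue,
                    "mark": HISTONE_MARKS[k % len(HISTONE_MARKS)],
                    "source": "synthetic",
                }
            )
    meta = FeatureMetadata(pd.DataFrame(meta_rows).set_index("feature_id"))
    matrix = pd.DataFrame(
        {fid: columns[fid] for fid in sorted(columns)},
        index=pd.RangeIndex(n, name="window_index"),
    )
    X = ChromatinMatrix(matrix)
    driver_latent = latents[config.driver_tissue]
    signal = (driver_latent - driver_latent.mean()) / driver_latent.std()
    truth = SimTruth(
        driver_tissue=config.driver_tissue,
        driver_feature_ids=sorted(
            f for f in columns if f.startswith(config.driver_tissue + "_")
        ),
        driver_signal=signal,
        latents=latents,
    )
    return X, meta, truth


def simulate_mutations(
    truth: SimTruth, config: SimConfig, sample_id: str = "sim_sample", seed: int | None = None
) -> MutationProfile:
    """Per-window mutation counts driven by the driver tissue's profile.

    counts_i ~ Poisson(mu_i) with mu = baseline * m / mean(m) and
    m = exp(b * z + eps), eps ~ Normal(0, noise_sd): the normalisation
    calibrates the realized mean density to ``baseline_density`` exactly
    in expectation.
    """
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "mutations", sample_id)
    )
    z = truth.driver_signal
    eps = rng.normal(0.0, config.noise_sd, size=z.shape)
    m = np.exp(config.effect_size * z + eps)
    mu = config.baseline_density * m / m.mean()
    counts = rng.poisson(mu)
    return MutationProfile(sample_id, counts)


# ---------------------------------------------------------------------------
# on-disk fixture


def _chrom_window_counts(config: SimConfig) -> list[int]:
    base, extra = divmod(config.n_windows, config.n_chromosomes)
    return [base + (1 if c < extra else 0) for c in range(config.n_chromosomes)]


def simulate_window_set(config: SimConfig, window_size: int = 1_000_000):
    """Windows over a toy multi-chromosome genome reproducing n_windows rows.

    Each synthetic autosome carries one fully excluded leading window and a
    trailing partial tile, so the exclusion and partial-drop code paths are
    exercised while the retained count stays exactly ``n_windows``.
    """
    sizes, exclusions = {}, []
    for c, k in enumerate(_chrom_window_counts(config)):
        chrom = f"chr{c + 1}"
        sizes[chrom] = (k + 1) * window_size + window_size // 2
        exclusions.append((chrom, 0, window_size))
    ws = build_windows(sizes, ExclusionSet(exclusions), window_size=window_size)
    assert len(ws) == config.n_windows
    return ws, sizes, exclusions


def write_fixture(out_dir, config: SimConfig, n_samples: int = 1) -> dict:
    """Write a complete, self-consistent input tree for the pipeline.

    Emits chrom_sizes.tsv, exclusions.bed, windows.bed, matrix.tsv,
    metadata.tsv, per-tissue enhancer BEDs, one variants TSV per sample and
    truth.json; everything parses back through the package's own readers,
    and re-counting the variant files reproduces the simulated profiles.
    """
    os.makedirs(out_dir, exist_ok=True)
    ws, sizes, exclusions = simulate_window_set(config)
    X, meta, truth = simulate_chromatin(config)

    with open(os.path.join(out_dir, "chrom_sizes.tsv"), "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    with open(os.path.join(out_dir, "exclusions.bed"), "w") as fh:
        for chrom, s, e in exclusions:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    write_windows(ws, os.path.join(out_dir, "windows.bed"))
    X.to_tsv(os.path.join(out_dir, "matrix.tsv"))
    meta.to_tsv(os.path.join(out_dir, "metadata.tsv"))

    # enhancer tracks: for each tissue, short intervals inside the windows
    # where that tissue's latent profile is strongest
    rng = np.random.default_rng(derive_seed(config.seed, "enhancers"))
    enhancer_paths = {}
    for tissue, latent in truth.latents.items():
        top = np.argsort(latent)[-max(1, config.n_windows // 10):]
        path = os.path.join(out_dir, f"enhancers_{tissue}.bed")
        with open(path, "w") as fh:
            for idx in sorted(top):
                w = ws.windows[idx]
                offset = int(rng.integers(0, ws.window_size - 2000))
                fh.write(f"{w.chrom}\t{w.start + offset}\t{w.start + offset + 2000}\n")
        enhancer_paths[tissue] = path

    sample_ids = []
    for s in range(n_samples):
        sample_id = f"sample{s + 1:02d}"
        profile = simulate_mutations(truth, config, sample_id)
        srng = np.random.default_rng(derive_seed(config.seed, "positions", s))
        with open(os.path.join(out_dir, f"variants_{sample_id}.tsv"), "w") as fh:
            for idx, count in enumerate(profile.counts):
                w = ws.windows[idx]
                for pos0 in sorted(srng.integers(w.start, w.end, int(count))):
                    fh.write(f"{w.chrom}\t{int(pos0) + 1}\n")
        sample_ids.append(sample_id)

    truth_doc = {
        "driver_tissue": truth.driver_tissue,
        "driver_feature_ids": truth.driver_feature_ids,
        "config": asdict(config),
        "samples": sample_ids,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth_doc, fh, indent=2)
    return truth_doc
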