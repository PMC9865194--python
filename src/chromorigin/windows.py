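"""Fixed-width autosomal genomic windows.

The whole pipeline operates on an ordered set of retained fixed-width
windows (1 Mb by default): mutation profiles, chromatin matrices and
region subsets are all indexed by the same window axis.  Windows are
tiled per autosome from position 0, the trailing partial tile is
dropped, and any window whose overlap with the exclusion intervals
(centromeres, telomeres, poorly mappable sequence) exceeds a configurable
fraction is removed.  Retained windows get dense indices 0..N-1.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

DEFAULT_WINDOW_SIZE = 1_000_000
DEFAULT_EXCLUDED_FRACTION_MAX = 0.5

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")


def is_autosome(chrom: str) -> bool:
    return _AUTOSOME_RE.match(chrom) is not None


def _chrom_sort_key(chrom: str) -> int:
    m = _AUTOSOME_RE.match(chrom)
    if m is None:
        raise ValueError(f"not an autosome name: {chrom!r}")
    return int(m.group(2))


@dataclass(frozen=True)
class GenomeWindow:
    """One retained window: ``[start, end)`` on ``chrom``, width == window size."""

    chrom: str
    start: int
    end: int
    index: int


@dataclass
class ExclusionSet:
    """Genomic intervals to subtract from the window grid (0-based half-open).

    Intervals may overlap; they are merged per chromosome before use.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    @classmethod
    def from_bed(cls, path) -> "ExclusionSet":
        return cls(read_bed3(path))

    def merged(self) -> dict[str, np.ndarray]:
        """Per-chromosome (k, 2) arrays of merged, sorted intervals."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            if end <= start:
                raise ValueError(f"interval end <= start: {(chrom, start, end)}")
            by_chrom.setdefault(chrom, []).append((start, end))
        out: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = np.asarray(merged, dtype=np.int64)
        return out


@dataclass
class WindowSet:
    """Ordered retained windows defining the row axis of every matrix."""

    windows: list[GenomeWindow]
    window_size: int = DEFAULT_WINDOW_SIZE
    genome_build: str = "GRCh37"
    excluded_fraction_max: float = DEFAULT_EXCLUDED_FRACTION_MAX

    def __post_init__(self) -> None:
        # tile ordinal (start // window_size) -> retained index, per chromosome
        self._lookup: dict[str, dict[int, int]] = {}
        for w in self.windows:
            self._lookup.setdefault(w.chrom, {})[w.start // self.window_size] = w.index

    def __len__(self) -> int:
        return len(self.windows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WindowSet):
            return NotImplemented
        return (
            self.windows == other.windows
            and self.window_size == other.window_size
            and self.genome_build == other.genome_build
        )

    def locate(self, chrom: str, pos0: int) -> int | None:
        """Retained-window index containing 0-based position, or None."""
        tiles = self._lookup.get(chrom)
        if tiles is None or pos0 < 0:
            return None
        return tiles.get(pos0 // self.window_size)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.window_size}:{self.genome_build}".encode())
        for w in self.windows:
            h.update(f"{w.chrom}:{w.start}:{w.end}:{w.index}".encode())
        return h.hexdigest()[:16]


def build_windows(
    chrom_sizes: dict[str, int],
    exclusions: ExclusionSet | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    excluded_fraction_max: float = DEFAULT_EXCLUDED_FRACTION_MAX,
    genome_build: str = "GRCh37",
) -> WindowSet:
    """Tile autosomes into fixed windows and drop heavily excluded ones.

    Each autosome is tiled from 0 in steps of ``window_size``; the trailing
    partial tile is dropped.  A window is retained iff the fraction of its
    bases covered by (merged) exclusion intervals is <= ``excluded_fraction_max``.
    Retained windows are ordered by natural chromosome order then start, and
    indexed densely.
    """
    if not chrom_sizes:
        raise ValueError("chrom_sizes is empty")
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    for chrom in chrom_sizes:
        if not is_autosome(chrom):
            raise ValueError(f"non-autosomal chromosome in chrom_sizes: {chrom!r}")
    merged = (exclusions or ExclusionSet()).merged()

    windows: list[GenomeWindow] = []
    idx = 0
    for chrom in sorted(chrom_sizes, key=_chrom_sort_key):
        length = int(chrom_sizes[chrom])
        ivs = merged.get(chrom)
        for start in range(0, length - window_size + 1, window_size):
            end = start + window_size
            if ivs is not None:
                overlap = np.minimum(ivs[:, 1], end) - np.maximum(ivs[:, 0], start)
                excluded = int(np.clip(overlap, 0, None).sum())
                if excluded / window_size > excluded_fraction_max:
                    continue
            windows.append(GenomeWindow(chrom, start, end, idx))
            idx += 1
    return WindowSet(windows, window_size, genome_build, excluded_fraction_max)


def write_windows(ws: WindowSet, path) -> None:
    """BED3 + index column, tab-separated, no header; byte-stable."""
    with open(path, "w") as fh:
        fh.write(f"#window_size={ws.window_size}\tgenome_build={ws.genome_build}\n")
        for w in ws.windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.index}\n")


def read_windows(path) -> WindowSet:
    window_size = None
    genome_build = "GRCh37"
    windows: list[GenomeWindow] = []
    seen_idx: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for part in line[1:].split("\t"):
                    key, _, val = part.partition("=")
                    if key == "window_size":
                        window_size = int(val)
                    elif key == "genome_build":
                        genome_build = val
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, index = fields
            try:
                start, end, index = int(start), int(end), int(index)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            if index in seen_idx:
                raise ValueError(f"{path}: line {lineno}: duplicated index {index}")
            seen_idx.add(index)
            windows.append(GenomeWindow(chrom, start, end, index))
    if window_size is None:
        if not windows:
            raise ValueError(f"{path}: no windows and no header")
        window_size = windows[0].end - windows[0].start
    for w in windows:
        if w.end - w.start != window_size:
            raise ValueError(f"window {w.index} width != window_size {window_size}")
    if sorted(seen_idx) != list(range(len(windows))):
        raise ValueError(f"{path}: window indices are not dense 0..N-1")
    return WindowSet(windows, window_size, genome_build)


def read_bed3(path) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader (extra columns ignored, track/browser lines skipped)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            out.append((fields[0], start, end))
    return out


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes
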