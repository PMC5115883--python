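"""1H NMR bucket preprocessing.

Converts bucketed spectra into the discretized ordinal features the models
consume: equidistant 0.04-ppm binning over 0.16-9.00 ppm, deletion of the
urea (5.45-6.48 ppm) and water (4.48-4.96 ppm) regions, integral
normalization of each spectrum to a constant total of 100, pareto scaling,
and 10-quantile discretization.

Buckets are half-open intervals ``[left, left + width)`` and are named by
their left edge rounded to two decimals ("bucket 3.16"), matching the
conventional ppm labelling of bucket tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DiscretizedDataset, VariableMeta, ValidationError

__all__ = [
    "SpectrumTable",
    "PreprocessConfig",
    "bin_spectrum",
    "bucket_edges",
    "bucket_name",
    "exclude_regions",
    "normalize_integral",
    "pareto_scale",
    "quantile_discretize",
    "preprocess_spectra",
    "read_spectra_csv",
]

#: ppm regions removed by default: urea, then residual water suppression.
DEFAULT_EXCLUDED_REGIONS: tuple[tuple[float, float], ...] = ((5.45, 6.48), (4.48, 4.96))


@dataclass
class SpectrumTable:
    """Subjects x buckets intensity table with explicit ppm bucket edges."""

    subjects: list
    ppm_edges: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.ppm_edges = np.asarray(self.ppm_edges, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.ppm_edges) <= 0):
            raise ValidationError("ppm_edges must be strictly increasing")
        if self.intensities.shape != (len(self.subjects), len(self.ppm_edges) - 1):
            raise ValidationError("intensity matrix shape does not match subjects x buckets")
        if not np.all(np.isfinite(self.intensities)) or np.any(self.intensities < 0):
            raise ValidationError("intensities must be finite and non-negative")

    @property
    def n_buckets(self) -> int:
        return len(self.ppm_edges) - 1

    @property
    def bucket_lefts(self) -> np.ndarray:
        return self.ppm_edges[:-1]


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing chain (defaults = standard chain)."""

    bin_width: float = 0.04
    ppm_lo: float = 0.16
    ppm_hi: float = 9.00
    excluded_regions: tuple = DEFAULT_EXCLUDED_REGIONS
    #: "overlap" removes any bucket with nonzero overlap with an excluded
    #: region (183 buckets survive on the default grid); "contained" removes
    #: only buckets lying entirely inside a region (184 survive).  The exact
    #: boundary convention of legacy bucket tables varies, hence the switch.
    overlap_rule: str = "overlap"
    integral_total: float = 100.0
    #: ddof for the pareto-scaling standard deviation: 1 = sample (default),
    #: 0 = population.
    sd_ddof: int = 1
    n_quantiles: int = 10


def bucket_edges(lo: float = 0.16, hi: float = 9.00, width: float = 0.04) -> np.ndarray:
    """Edges of the equidistant bucket grid covering ``[lo, hi)``."""
    if width <= 0 or lo >= hi:
        raise ValueError("need width > 0 and lo < hi")
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def bucket_name(left_edge: float) -> str:
    return f"bucket {left_edge:.2f}"


def bin_spectrum(
    ppm_axis: np.ndarray,
    signal: np.ndarray,
    width: float = 0.04,
    lo: float = 0.16,
    hi: float = 9.00,
) -> np.ndarray:
    """Integrate a sampled spectrum into equidistant half-open ppm buckets.

    Each bucket value is the sum of the signal samples whose ppm position
    falls in ``[edge, edge + width)``.
    """
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if ppm_axis.ndim != 1 or ppm_axis.shape != signal.shape:
        raise ValueError("ppm_axis and signal must be 1-D and congruent")
    if np.any(np.diff(ppm_axis) < 0):
        raise ValueError("ppm_axis must be sorted")
    edges = bucket_edges(lo, hi, width)
    inside = (ppm_axis >= edges[0]) & (ppm_axis < edges[-1])
    if not inside.any():
        raise ValueError("ppm axis has no overlap with the bucket range")
    idx = np.searchsorted(edges, ppm_axis[inside], side="right") - 1
    return np.bincount(idx, weights=signal[inside], minlength=len(edges) - 1)


def exclude_regions(
    table: SpectrumTable,
    regions=DEFAULT_EXCLUDED_REGIONS,
    overlap_rule: str = "overlap",
) -> SpectrumTable:
    """Delete buckets hit by the excluded ppm regions.

    ``overlap_rule="overlap"`` drops a bucket when its half-open interval has
    nonzero intersection with a region; ``"contained"`` drops it only when
    the bucket lies entirely inside the region.
    """
    if overlap_rule not in ("overlap", "contained"):
        raise ValueError(f"unknown overlap_rule {overlap_rule!r}")
    lefts = table.ppm_edges[:-1]
    rights = table.ppm_edges[1:]
    drop = np.zeros(table.n_buckets, dtype=bool)
    for lo, hi in regions:
        if lo >= hi:
            raise ValueError(f"malformed region ({lo}, {hi})")
        if overlap_rule == "overlap":
            drop |= (rights > lo) & (lefts < hi)
        else:
            drop |= (lefts >= lo) & (rights <= hi)
    keep = ~drop
    # buckets keep their ppm labels: edges become per-bucket (left, right)
    return _irregular_subset(table, keep)


def _irregular_subset(table: SpectrumTable, keep: np.ndarray) -> SpectrumTable:
    """Subset buckets; represent a possibly gapped grid by keeping the left
    edges and appending the final right edge per contiguous run."""
    lefts = table.ppm_edges[:-1][keep]
    rights = table.ppm_edges[1:][keep]
    # a gapped grid cannot be represented by a single monotone edge vector,
    # so bypass the regular constructor and keep per-bucket (left, right)
    new = SpectrumTable.__new__(SpectrumTable)
    new.subjects = table.subjects
    new.ppm_edges = np.append(lefts, rights[-1]) if len(lefts) else np.array([0.0])
    new.intensities = table.intensities[:, keep]
    new._bucket_lefts = lefts
    new._bucket_rights = rights
    return new


def _table_lefts(table: SpectrumTable) -> np.ndarray:
    return getattr(table, "_bucket_lefts", table.ppm_edges[:-1])


def normalize_integral(matrix: np.ndarray, total: float = 100.0, subjects=None) -> np.ndarray:
    """Rescale each row (spectrum) to a constant integral ``total``."""
    matrix = np.asarray(matrix, dtype=float)
    sums = matrix.sum(axis=1)
    bad = np.nonzero(sums <= 0)[0]
    if len(bad):
        who = subjects[bad[0]] if subjects is not None else int(bad[0])
        raise ValidationError(f"subject {who!r} has a non-positive spectrum integral")
    return matrix * (total / sums)[:, None]


def pareto_scale(matrix: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Mean-center each column and divide by the square root of its standard
    deviation; zero-variance columns map to all-zeros."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("pareto scaling needs at least 2 subjects")
    centered = matrix - matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=ddof)
    out = np.zeros_like(centered)
    nz = sd > 0
    out[:, nz] = centered[:, nz] / np.sqrt(sd[nz])
    return out


def quantile_discretize(matrix: np.ndarray, q: int = 10) -> np.ndarray:
    """Discretize each column into ``q`` quantile bins, codes ``1..q``.

    Interior bin edges sit at the ``i/q`` empirical quantiles (linear
    interpolation); duplicate edges are merged, so a heavily tied column may
    occupy fewer than ``q`` codes.  Intervals are right-closed: a value equal
    to an edge falls in the lower bin.  Codes are monotone in the values.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    matrix = np.asarray(matrix, dtype=float)
    codes = np.empty(matrix.shape, dtype=np.int64)
    probs = np.arange(1, q) / q
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        edges = np.unique(np.quantile(col, probs))
        # right-closed: count of edges strictly below the value
        codes[:, j] = np.searchsorted(edges, col, side="left") + 1
    return codes


def read_spectra_csv(path) -> SpectrumTable:
    """Read a subjects x buckets CSV whose header row holds the bucket left
    edges in ppm (equidistant grid assumed for the final right edge)."""
    df = pd.read_csv(path, index_col=0)
    lefts = np.array([float(c) for c in df.columns])
    widths = np.diff(lefts)
    step = widths[0] if len(widths) else 0.04
    edges = np.append(lefts, lefts[-1] + step)
    return SpectrumTable(list(df.index), edges, df.to_numpy(dtype=float))


def preprocess_spectra(
    table: SpectrumTable,
    target: pd.Series,
    config: PreprocessConfig | None = None,
    modalities=None,
) -> DiscretizedDataset:
    """Full chain: rebin -> exclude regions -> normalize -> pareto -> discretize.

    ``table`` may be sampled on any grid finer than or equal to the bucket
    grid; it is first re-integrated onto the configured equidistant buckets.
    Subject count and order are preserved throughout.
    """
    cfg = config or PreprocessConfig()
    centers = 0.5 * (table.ppm_edges[:-1] + table.ppm_edges[1:])
    binned = np.stack(
        [
            bin_spectrum(centers, row, cfg.bin_width, cfg.ppm_lo, cfg.ppm_hi)
            for row in table.intensities
        ]
    )
    grid = SpectrumTable(table.subjects, bucket_edges(cfg.ppm_lo, cfg.ppm_hi, cfg.bin_width), binned)
    reduced = exclude_regions(grid, cfg.excluded_regions, cfg.overlap_rule)
    lefts = _table_lefts(reduced)
    norm = normalize_integral(reduced.intensities, cfg.integral_total, reduced.subjects)
    scaled = pareto_scale(norm, ddof=cfg.sd_ddof)
    codes = quantile_discretize(scaled, cfg.n_quantiles)

    names = [bucket_name(l) for l in lefts]
    variables = [
        VariableMeta(name=n, kind="ordinal", n_levels=cfg.n_quantiles, origin="bucket")
        for n in names
    ]
    data = pd.DataFrame(codes, index=table.subjects, columns=names)
    target = target.reindex(data.index)
    kwargs = {} if modalities is None else {"modalities": modalities}
    return DiscretizedDataset(data=data, variables=variables, target=target, **kwargs)
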