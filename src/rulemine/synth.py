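"""Synthetic discretized cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a small CKD metabolomics
cohort: 110 subjects, 184 ordinal ppm-bucket variables discretized into 10
quantile bins, a 24/86 class imbalance (eGFR >= 60 vs < 60 ml/min/1.73m^2),
a couple of clinical variables, plus planted effects of two kinds:

* **1D marginal shifts** — a bucket whose renal-failure subjects fall in an
  enriched bin range with a given probability, mirrored to the opposite
  range for the other class (low concentration in one class, high in the
  other).
* **2D interactions with balanced margins** — a bucket pair whose joint
  distribution concentrates on the low-low/high-high diagonal corners for
  one class and on the off-diagonal corners for the other, while each
  margin stays near-uniform, so 1D mining is blind to the pair and only the
  1&2D model can recover it.

Everything is driven by one seed; a fixed spec and seed reproduce the
dataset bit for bit.  The ground truth is returned as planted rules so
recovery can be scored mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import DEFAULT_MODALITIES, DiscretizedDataset, VariableMeta
from .mining import Condition, Rule, RuleSet
from .preprocess import SpectrumTable

__all__ = ["SyntheticSpec", "generate", "generate_spectra", "bucket_variable_name"]


def bucket_variable_name(i: int) -> str:
    """Stable synthetic bucket names on a ppm-like grid."""
    return f"bucket {0.16 + 0.04 * i:.2f}"


@dataclass
class SyntheticSpec:
    """Study-condition defaults: 110 subjects, 184 buckets x 10 bins, 24/86
    class split, one age-like ordinal and one binary nominal clinical
    variable."""

    n_subjects: int = 110
    n_buckets: int = 184
    n_bins: int = 10
    #: (renal failure = below60, no failure = at_least_60)
    class_sizes: tuple = (86, 24)
    modalities: tuple = DEFAULT_MODALITIES
    #: (bucket index, (lo, hi) enriched range for below60, enrichment prob)
    planted_1d: tuple = ()
    #: ((bucket i, bucket j), corner prob, marginally_balanced)
    planted_2d: tuple = ()
    n_clinical: int = 2
    #: P(upper-half age bins | below60) for the age-like clinical variable
    clinical_association: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if sum(self.class_sizes) != self.n_subjects:
            raise ValueError("class sizes must sum to n_subjects")
        for idx, (lo, hi), p in self.planted_1d:
            if not (0 <= idx < self.n_buckets):
                raise ValueError(f"planted 1D index {idx} out of range")
            if not (1 <= lo <= hi <= self.n_bins):
                raise ValueError(f"planted range [{lo}, {hi}] invalid")
            if not (0 < p < 1):
                raise ValueError("enrichment probabilities must lie in (0, 1)")
        for (i, j), p, _bal in self.planted_2d:
            if i == j or not (0 <= i < self.n_buckets and 0 <= j < self.n_buckets):
                raise ValueError(f"planted 2D pair ({i}, {j}) invalid")
            if not (0 < p < 1):
                raise ValueError("corner probabilities must lie in (0, 1)")


def _mirror_range(lo: int, hi: int, k: int) -> tuple[int, int]:
    return k + 1 - hi, k + 1 - lo


def generate(spec: SyntheticSpec) -> tuple[DiscretizedDataset, RuleSet]:
    """Draw one dataset; returns ``(dataset, ground_truth)`` where the
    ground truth lists the planted rules (with their realized coverage and
    z computed on the generated data)."""
    rng = np.random.default_rng(spec.seed)
    below, atleast = spec.modalities
    labels = np.array([below] * spec.class_sizes[0] + [atleast] * spec.class_sizes[1])
    rng.shuffle(labels)
    is_below = labels == below
    n, k = spec.n_subjects, spec.n_bins

    codes = rng.integers(1, k + 1, size=(n, spec.n_buckets))

    planted_1d_vars = {}
    for idx, (lo, hi), p in spec.planted_1d:
        col = rng.integers(1, k + 1, size=n)
        mlo, mhi = _mirror_range(lo, hi, k)
        enrich = rng.random(n) < p
        col[is_below & enrich] = rng.integers(lo, hi + 1, size=int((is_below & enrich).sum()))
        col[~is_below & enrich] = rng.integers(mlo, mhi + 1, size=int((~is_below & enrich).sum()))
        codes[:, idx] = col
        planted_1d_vars[idx] = (lo, hi)

    planted_2d_pairs = []
    half = k // 2
    for (i, j), p, balanced in spec.planted_2d:
        ci = rng.integers(1, k + 1, size=n)
        cj = rng.integers(1, k + 1, size=n)
        in_corner = rng.random(n) < p
        low = rng.random(n) < 0.5  # which corner along the chosen diagonal
        for s in range(n):
            if not in_corner[s]:
                continue
            if is_below[s]:
                # main diagonal: low-low or high-high
                a = rng.integers(1, half + 1) if low[s] else rng.integers(half + 1, k + 1)
                b = rng.integers(1, half + 1) if low[s] else rng.integers(half + 1, k + 1)
            elif balanced:
                # anti-diagonal keeps the margins of both classes uniform
                a = rng.integers(1, half + 1) if low[s] else rng.integers(half + 1, k + 1)
                b = rng.integers(half + 1, k + 1) if low[s] else rng.integers(1, half + 1)
            else:
                continue
            ci[s], cj[s] = a, b
        codes[:, i] = ci
        codes[:, j] = cj
        planted_2d_pairs.append((i, j))

    names = [bucket_variable_name(i) for i in range(spec.n_buckets)]
    variables = [VariableMeta(nm, "ordinal", k, origin="bucket") for nm in names]
    data = {nm: codes[:, i] for i, nm in enumerate(names)}

    # clinical variables: age-like ordinal enriched in upper bins for the
    # renal-failure class, and a binary nominal with no planted association
    if spec.n_clinical >= 1:
        age = rng.integers(1, k + 1, size=n)
        older = rng.random(n) < spec.clinical_association
        age[is_below & older] = rng.integers(half + 1, k + 1, size=int((is_below & older).sum()))
        age[~is_below & older] = rng.integers(1, half + 1, size=int((~is_below & older).sum()))
        variables.append(VariableMeta("Age", "ordinal", k, origin="clinical"))
        data["Age"] = age
    if spec.n_clinical >= 2:
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        variables.append(VariableMeta("Sex", "nominal", 2, level_labels=("F", "M"), origin="demographic"))
        data["Sex"] = sex

    subjects = [f"subject_{s:03d}" for s in range(n)]
    df = pd.DataFrame(data, index=subjects)[[v.name for v in variables]]
    target = pd.Series(labels, index=subjects)
    ds = DiscretizedDataset(data=df, variables=variables, target=target, modalities=spec.modalities)

    truth = _ground_truth(spec, ds, planted_1d_vars, planted_2d_pairs, half)
    return ds, truth


def _ground_truth(spec, ds, planted_1d_vars, planted_2d_pairs, half) -> RuleSet:
    from .mining import z_score  # local import to avoid cycle at module load

    rules = []
    below, atleast = spec.modalities
    k = spec.n_bins

    def _realized(conds, modality):
        mask = np.ones(ds.n_subjects, dtype=bool)
        for c in conds:
            mask &= c.mask(ds)
        y = ds.modality_indicator(modality)
        cov = int(mask.sum())
        msize = int((mask & y).sum())
        z = z_score(mask, modality, ds) if cov else 0.0
        return Rule(conditions=tuple(conds), modality=modality, coverage=cov, modality_size=msize, z=z)

    for idx, (lo, hi) in planted_1d_vars.items():
        name = bucket_variable_name(idx)
        mlo, mhi = _mirror_range(lo, hi, k)
        rules.append(_realized([Condition(name, lo=lo, hi=hi)], below))
        rules.append(_realized([Condition(name, lo=mlo, hi=mhi)], atleast))
    for i, j in planted_2d_pairs:
        ni, nj = bucket_variable_name(i), bucket_variable_name(j)
        rules.append(_realized([Condition(ni, lo=1, hi=half), Condition(nj, lo=1, hi=half)], below))
        rules.append(_realized([Condition(ni, lo=half + 1, hi=k), Condition(nj, lo=half + 1, hi=k)], below))
        rules.append(_realized([Condition(ni, lo=1, hi=half), Condition(nj, lo=half + 1, hi=k)], atleast))
        rules.append(_realized([Condition(ni, lo=half + 1, hi=k), Condition(nj, lo=1, hi=half)], atleast))
    return RuleSet(rules=rules, provenance={"planted": True, "seed": spec.seed})


# ---------------------------------------------------------------------------
# Synthetic spectra


def _lorentzian(ppm, center, gamma):
    return gamma**2 / ((ppm - center) ** 2 + gamma**2)


def generate_spectra(
    spec: SyntheticSpec,
    peaks=None,
    sampling: float = 0.005,
    gamma: float = 0.01,
    baseline: float = 0.5,
    bio_sd: float = 0.2,
    noise: float = 0.01,
    lo: float = 0.16,
    hi: float = 9.00,
) -> tuple[SpectrumTable, pd.Series, dict]:
    """Smooth synthetic spectra as sums of Lorentzian peaks.

    ``peaks`` is a list of ``(ppm_center, amp_below60, amp_at_least_60)``;
    default: a discriminating peak at 3.16 ppm (2:1 amplitude between
    classes) plus two non-discriminating peaks.  The baseline emulates the
    dense unresolved metabolite background: it carries per-subject,
    per-bucket biological variability (relative sd ``bio_sd``), without
    which the integral-normalization closure of a single changing peak
    would leak a spurious class signal into every bucket.  Returns the
    finely sampled spectrum table, the target labels, and a ground-truth
    dict naming the discriminating peak positions.  Pushing the table
    through the preprocessing chain recovers the planted class signal.
    """
    if peaks is None:
        peaks = [(3.16, 2.0, 1.0), (1.00, 1.0, 1.0), (7.50, 0.8, 0.8)]
    rng = np.random.default_rng(spec.seed)
    below, atleast = spec.modalities
    labels = np.array([below] * spec.class_sizes[0] + [atleast] * spec.class_sizes[1])
    rng.shuffle(labels)

    edges = np.arange(lo, hi + sampling / 2, sampling)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # biological variability is correlated within a 0.04-ppm bucket
    chunk = max(int(round(0.04 / sampling)), 1)
    n_chunks = int(np.ceil(len(centers) / chunk))
    spectra = np.zeros((spec.n_subjects, len(centers)))
    for s in range(spec.n_subjects):
        factors = np.clip(1.0 + bio_sd * rng.standard_normal(n_chunks), 0.1, None)
        row = baseline * np.repeat(factors, chunk)[: len(centers)]
        for ppm0, amp_b, amp_a in peaks:
            amp = amp_b if labels[s] == below else amp_a
            amp *= 1.0 + 0.1 * rng.standard_normal()  # concentration variability
            row += max(amp, 0.0) * _lorentzian(centers, ppm0, gamma)
        row += noise * rng.random(len(centers))
        spectra[s] = np.clip(row, 0.0, None)

    subjects = [f"subject_{s:03d}" for s in range(spec.n_subjects)]
    table = SpectrumTable(subjects, edges, spectra)
    target = pd.Series(labels, index=subjects)
    truth = {
        "discriminating_ppm": [p for p, ab, aa in peaks if ab != aa],
        "peaks": peaks,
    }
    return table, target, truth
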