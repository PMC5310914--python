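"""A damage-robust statistic for the TCC>T-type signature in ancient samples.

Ancient DNA carries cytosine-deamination damage that inflates every C>T
class, so a naive signature-1 intensity cannot be compared between ancient
and present-day samples. The corrected log-ratio

    M = log2[ (X_TCC X_ACC X_TCT X_CCC) / (X_TCA X_ACA X_TCA X_CCA) ]

(all eight classes C>T; TCA>T enters the denominator twice) pairs each
signature context with a control context so that a uniform multiplicative
inflation of all C>T counts cancels exactly: both products contain four C>T
intensities. M is reported normalized so that an African reference panel
has mean 0 and standard deviation 1, with bootstrap quantiles from
multinomial resampling of the class counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import Reference, VariantPanel
from .variant_spectrum import (
    CLASS_INDEX,
    LABEL_INDEX,
    SpectrumCounts,
    iter_classified_variants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MStatistic",
    "m_statistic",
    "m_from_counts",
    "normalize_m",
    "bootstrap_m",
    "ancient_site_filter",
]

#: numerator (signature) and denominator (control) classes; TCA>T twice.
NUMERATOR_CLASSES = ("TCC>T", "ACC>T", "TCT>T", "CCC>T")
DENOMINATOR_CLASSES = ("TCA>T", "ACA>T", "TCA>T", "CCA>T")

_NUM_IDX = np.array([LABEL_INDEX[l] for l in NUMERATOR_CLASSES])
_DEN_IDX = np.array([LABEL_INDEX[l] for l in DENOMINATOR_CLASSES])
_REQUIRED = sorted(set(NUMERATOR_CLASSES) | set(DENOMINATOR_CLASSES))


@dataclass
class MStatistic:
    """Raw and reference-normalized M with bootstrap quantiles."""

    raw: float
    normalized: float
    reference_mean: float
    reference_sd: float
    bootstrap_quantiles: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_quantiles is not None:
            q05, q95 = self.bootstrap_quantiles
            if q05 > q95:
                raise ValueError("bootstrap quantiles out of order")


def m_statistic(x: Mapping[str, float] | np.ndarray) -> float:
    """Raw M from one sample's class intensities.

    Accepts a mapping of class label -> intensity (all eight required C>T
    classes present) or a full 96-vector in canonical class order. Because M
    is a ratio of products of intensities from the same sample, any
    per-sample normalization of the counts cancels.
    """
    if isinstance(x, Mapping):
        missing = [l for l in _REQUIRED if l not in x]
        if missing:
            raise ValueError(f"missing class intensities: {missing}")
        num = np.prod([float(x[l]) for l in NUMERATOR_CLASSES])
        den = np.prod([float(x[l]) for l in DENOMINATOR_CLASSES])
    else:
        v = np.asarray(x, dtype=float)
        if v.shape != (96,):
            raise ValueError("expected a 96-vector of class intensities")
        num = float(np.prod(v[_NUM_IDX]))
        den = float(np.prod(v[_DEN_IDX]))
    if num <= 0 or den <= 0:
        raise ValueError(
            "zero intensity among the eight M classes; apply the pseudocount "
            "policy (m_from_counts) or supply positive intensities"
        )
    return float(np.log2(num / den))


def m_from_counts(counts: np.ndarray, pseudocount: float = 0.5) -> float:
    """Raw M from a 96-vector of raw counts.

    If any of the eight required classes has zero count, ``pseudocount`` is
    added to all eight (logged), keeping the statistic defined.
    """
    v = np.asarray(counts, dtype=float).copy()
    if v.shape != (96,):
        raise ValueError("expected a 96-vector of class counts")
    idx = np.concatenate([_NUM_IDX, _DEN_IDX])
    if (v[idx] == 0).any():
        logger.info("zero count among M classes; adding pseudocount %.2f", pseudocount)
        v[np.unique(idx)] += pseudocount
    return m_statistic(v)


def normalize_m(
    raw_values: Sequence[float] | np.ndarray,
    reference_indices: Sequence[int] | np.ndarray,
) -> list[MStatistic]:
    """Normalize raw per-sample M values so the reference panel (e.g. the
    African samples) has mean 0 and standard deviation 1."""
    raw = np.asarray(raw_values, dtype=float)
    ref = raw[np.asarray(reference_indices, dtype=int)]
    if len(ref) < 2:
        raise ValueError("reference panel needs at least two samples")
    mean, sd = float(ref.mean()), float(ref.std(ddof=1))
    if sd == 0:
        raise ValueError("zero variance in reference panel")
    return [MStatistic(float(r), float((r - mean) / sd), mean, sd) for r in raw]


def bootstrap_m(
    counts: np.ndarray,
    n_boot: int,
    seed: int | None,
    reference_mean: float,
    reference_sd: float,
    method: str = "multinomial",
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """5% and 95% bootstrap quantiles of normalized M for one sample.

    Replicates resample the 96 class counts — multinomially with the
    observed total preserved (default), or independently Poisson per class —
    and recompute M with the same pseudocount policy.
    """
    v = np.asarray(counts)
    if v.shape != (96,):
        raise ValueError("expected a 96-vector of class counts")
    if (v < 0).any() or not np.allclose(v, np.round(v)):
        raise ValueError("counts must be non-negative integers")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if reference_sd <= 0:
        raise ValueError("reference sd must be positive")
    rng = np.random.default_rng(seed)
    total = int(v.sum())
    if total == 0:
        raise ValueError("sample has no counts")
    p = v / total
    reps = np.empty(n_boot)
    n_pseudo = 0
    for b in range(n_boot):
        if method == "multinomial":
            c = rng.multinomial(total, p)
        elif method == "poisson":
            c = rng.poisson(v)
        else:
            raise ValueError(f"unknown bootstrap method {method!r}")
        idx = np.concatenate([_NUM_IDX, _DEN_IDX])
        if (c[idx] == 0).any():
            n_pseudo += 1
        reps[b] = (m_from_counts(c, pseudocount) - reference_mean) / reference_sd
    if n_pseudo:
        logger.info("%d/%d replicates needed the pseudocount", n_pseudo, n_boot)
    q05, q95 = np.quantile(reps, [0.05, 0.95])
    return float(q05), float(q95)


def ancient_site_filter(
    ancient_het_sites: Sequence[tuple[str, int]],
    panel: VariantPanel,
    reference: Reference,
    stratum: str = "f1",
) -> np.ndarray:
    """Class counts for an ancient sample restricted to panel singletons.

    Only ancient heterozygous sites that coincide with sites carrying a
    single derived copy (one heterozygote) in the panel are counted; each
    contributes one mutation to its class. This confines the comparison to
    recent variation while the paired-control structure of M absorbs the
    residual damage."""
    from .variant_spectrum import _stratum_bounds

    lo, hi = _stratum_bounds(stratum, 2 * panel.n_samples)
    wanted = set(ancient_het_sites)
    counts = np.zeros(96, dtype=np.int64)
    positions = panel.variants["pos"]
    chroms = panel.variants["chrom"]
    n_hit = 0
    for cv in iter_classified_variants(panel, reference):
        if not lo <= cv.total_derived <= hi or cv.total_derived >= 2 * panel.n_samples:
            continue
        key = (chroms.iloc[cv.index], int(positions.iloc[cv.index]))
        if key in wanted:
            counts[CLASS_INDEX[cv.mclass]] += 1
            n_hit += 1
    if n_hit == 0:
        raise ValueError("no overlap between ancient het sites and panel singletons")
    return counts
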