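"""Stratification of classified mutations by genomic features.

Covers the three feature analyses: transcriptional strand (the
untranscribed/transcribed log-ratio diagnostic of transcription-coupled
repair), methylation state (rate ratio at high- vs low-methylation CpG
sites), and decile tracks (background-selection B statistic or
recombination-rate deciles), plus Fisher's exact test on 2x2 tables.

For strand bias, mutations are *not* collapsed with their reverse
complements: a pyrimidine-class mutation observed with its C/T on the +
strand of a minus-strand-transcribed region lies on the untranscribed
(coding) strand. Positions transcribed on both strands or neither are
excluded from bias counting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Reference, VariantPanel
from .variant_spectrum import (
    CLASS_INDEX,
    MutationClass,
    SignatureDefinition,
    Stratum,
    _stratum_bounds,
    iter_classified_variants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IntervalTrack",
    "strand_classify",
    "strand_bias",
    "StrandBiasResult",
    "methylation_ratio",
    "MethylationRatio",
    "fisher_2x2",
    "decile_stratify",
    "StratifiedCounts",
    "strand_bias_tests",
]


class IntervalTrack:
    """Labeled half-open intervals with fast per-position lookup.

    Intervals must be non-overlapping (as produced by the strand-flattening
    step or a decile track); positions outside any interval get ``default``.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]], default: str = "none"):
        self.default = default
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._labels: dict[str, list[str]] = {}
        by_chrom: dict[str, list] = {}
        for chrom, start, end, label in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, str(label)))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping intervals on {chrom} at {s2}; flatten first"
                    )
            self._starts[chrom] = np.array([iv[0] for iv in ivs])
            self._ends[chrom] = np.array([iv[1] for iv in ivs])
            self._labels[chrom] = [iv[2] for iv in ivs]

    def label_at(self, chrom: str, pos: int) -> str:
        """Label at a 1-based position."""
        if chrom not in self._starts:
            return self.default
        i = int(np.searchsorted(self._starts[chrom], pos - 1, side="right")) - 1
        if i >= 0 and pos - 1 < self._ends[chrom][i]:
            return self._labels[chrom][i]
        return self.default

    @property
    def labels(self) -> set[str]:
        return {l for ls in self._labels.values() for l in ls}


def strand_classify(
    positions: Sequence[tuple[str, int]], track: IntervalTrack, reference: Reference | None = None
) -> list[str]:
    """Label 1-based positions as +, -, both or none per the
    union-of-transcripts rule (the track must already be flattened)."""
    out = []
    for chrom, pos in positions:
        if reference is not None:
            if chrom not in reference.sequences or not 1 <= pos <= len(reference[chrom]):
                raise ValueError(f"position {chrom}:{pos} outside the reference")
        out.append(track.label_at(chrom, pos))
    return out


@dataclass
class StrandBiasResult:
    """Per-sample untranscribed/transcribed counts and log-ratio."""

    count_untranscribed: np.ndarray
    count_transcribed: np.ndarray
    log_ratio: np.ndarray
    samples: pd.DataFrame
    log_base: float = math.e
    pseudocount_used: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": list(self.samples["sample"]),
                "untranscribed": self.count_untranscribed,
                "transcribed": self.count_transcribed,
                "log_ratio": self.log_ratio,
            }
        )


def _log_ratio(untx: np.ndarray, tx: np.ndarray, base: float) -> tuple[np.ndarray, np.ndarray]:
    """Haldane policy: add 0.5 to both counts only where either is zero."""
    untx = untx.astype(float)
    tx = tx.astype(float)
    needs = (untx == 0) | (tx == 0)
    if needs.any():
        logger.info("pseudocount 0.5 applied to %d sample(s)", int(needs.sum()))
    u = np.where(needs, untx + 0.5, untx)
    t = np.where(needs, tx + 0.5, tx)
    return np.log(u / t) / math.log(base), needs


def strand_bias(
    panel: VariantPanel,
    reference: Reference,
    strand_track: IntervalTrack,
    class_set: Iterable[MutationClass] | SignatureDefinition,
    stratum: Stratum = "f2",
    log_base: float = math.e,
) -> StrandBiasResult:
    """Per-sample log-ratio of mutations on the untranscribed versus
    transcribed strand for a set of pyrimidine-centered classes.

    A positive value means the pyrimidine-strand mutation (e.g. C>T) is more
    common on the untranscribed (coding) strand than its purine counterpart.
    Positions labeled "both" or "none" are ignored.
    """
    classes = class_set.classes if isinstance(class_set, SignatureDefinition) else set(class_set)
    targets = {CLASS_INDEX[c] for c in classes}
    lo, hi = _stratum_bounds(stratum, 2 * panel.n_samples)
    untx = np.zeros(panel.n_samples, dtype=np.int64)
    tx = np.zeros(panel.n_samples, dtype=np.int64)
    positions = panel.variants["pos"]
    chroms = panel.variants["chrom"]
    for cv in iter_classified_variants(panel, reference):
        if CLASS_INDEX[cv.mclass] not in targets:
            continue
        if not lo <= cv.total_derived <= hi or cv.total_derived >= 2 * panel.n_samples:
            continue
        label = strand_track.label_at(chroms.iloc[cv.index], int(positions.iloc[cv.index]))
        if label not in ("+", "-"):
            continue
        # pyrimidine on + strand & region transcribed on -  -> untranscribed
        pyr_on_plus = not cv.flipped
        on_untranscribed = (pyr_on_plus and label == "-") or (not pyr_on_plus and label == "+")
        if on_untranscribed:
            untx += cv.derived_counts
        else:
            tx += cv.derived_counts
    log_ratio, used = _log_ratio(untx, tx, log_base)
    return StrandBiasResult(untx, tx, log_ratio, panel.samples.copy(), log_base, used)


@dataclass
class MethylationRatio:
    rate_high: float
    rate_low: float
    ratio: float
    n_high_mutations: int
    n_low_mutations: int
    infinite: bool = False


def methylation_ratio(
    panel: VariantPanel,
    reference: Reference,
    high_sites: Sequence[tuple[str, int]],
    low_sites: Sequence[tuple[str, int]],
    class_set: Iterable[MutationClass] | SignatureDefinition,
    stratum: Stratum = "f2",
) -> MethylationRatio:
    """Rate ratio of class-set mutations at high- versus low-methylation
    sites, normalizing each count by the size of its site list."""
    high = set(high_sites)
    low = set(low_sites)
    if high & low:
        raise ValueError("high and low site lists must be disjoint")
    if not high or not low:
        raise ValueError("site lists must be non-empty")
    classes = class_set.classes if isinstance(class_set, SignatureDefinition) else set(class_set)
    targets = {CLASS_INDEX[c] for c in classes}
    lo, hi = _stratum_bounds(stratum, 2 * panel.n_samples)
    n_high = n_low = 0
    positions = panel.variants["pos"]
    chroms = panel.variants["chrom"]
    for cv in iter_classified_variants(panel, reference):
        if CLASS_INDEX[cv.mclass] not in targets:
            continue
        if not lo <= cv.total_derived <= hi or cv.total_derived >= 2 * panel.n_samples:
            continue
        key = (chroms.iloc[cv.index], int(positions.iloc[cv.index]))
        if key in high:
            n_high += 1
        elif key in low:
            n_low += 1
    rate_high = n_high / len(high)
    rate_low = n_low / len(low)
    if rate_low == 0:
        logger.warning("no class mutations at low-methylation sites: infinite ratio")
        return MethylationRatio(rate_high, 0.0, math.inf, n_high, n_low, infinite=True)
    return MethylationRatio(rate_high, rate_low, rate_high / rate_low, n_high, n_low)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative integers
    (sum of hypergeometric probabilities <= the observed table's)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = t.astype(np.int64)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class StratifiedCounts:
    """Counts by (stratum label, group): all mutations and class-set
    mutations, with per-cell class-set proportions."""

    table: pd.DataFrame  # columns: stratum, group, n_total, n_class, proportion

    def proportions(self) -> pd.DataFrame:
        return self.table.pivot(index="stratum", columns="group", values="proportion")

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def decile_stratify(
    panel: VariantPanel,
    reference: Reference,
    decile_track: IntervalTrack,
    class_set: Iterable[MutationClass] | SignatureDefinition,
    groups: Mapping[str, Sequence[int]],
    stratum: Stratum = "f2",
) -> StratifiedCounts:
    """Count mutations per track stratum (decile) per sample group, and the
    per-cell proportion in the class set. Uncovered positions are skipped
    (logged); a cell with no mutations reports proportion 0."""
    classes = class_set.classes if isinstance(class_set, SignatureDefinition) else set(class_set)
    targets = {CLASS_INDEX[c] for c in classes}
    group_idx = {g: np.asarray(idx, dtype=int) for g, idx in groups.items()}
    strata = sorted(decile_track.labels, key=lambda x: (len(x), x))
    for s in strata:
        if not s.isdigit() or not 0 <= int(s) <= 9:
            raise ValueError(f"malformed decile label {s!r}")
    lo, hi = _stratum_bounds(stratum, 2 * panel.n_samples)
    totals = {(s, g): 0 for s in strata for g in group_idx}
    in_class = {(s, g): 0 for s in strata for g in group_idx}
    n_uncovered = 0
    positions = panel.variants["pos"]
    chroms = panel.variants["chrom"]
    for cv in iter_classified_variants(panel, reference):
        if not lo <= cv.total_derived <= hi or cv.total_derived >= 2 * panel.n_samples:
            continue
        label = decile_track.label_at(chroms.iloc[cv.index], int(positions.iloc[cv.index]))
        if label == decile_track.default:
            n_uncovered += 1
            continue
        hit = CLASS_INDEX[cv.mclass] in targets
        for g, idx in group_idx.items():
            w = int(cv.derived_counts[idx].sum())
            if w:
                totals[(label, g)] += w
                if hit:
                    in_class[(label, g)] += w
    if n_uncovered:
        logger.warning("%d variant(s) outside the decile track skipped", n_uncovered)
    rows = []
    for s in strata:
        for g in group_idx:
            tot = totals[(s, g)]
            cls = in_class[(s, g)]
            rows.append((s, g, tot, cls, cls / tot if tot else 0.0))
    return StratifiedCounts(
        pd.DataFrame(rows, columns=["stratum", "group", "n_total", "n_class", "proportion"])
    )


def strand_bias_tests(
    result: StrandBiasResult, groups: Mapping[str, Sequence[int]]
) -> dict[str, float]:
    """Summary tests on per-sample log-ratios: one-way ANOVA across all
    groups, and a Welch t-test between the first two groups given."""
    arrays = [np.asarray(result.log_ratio)[np.asarray(idx, int)] for idx in groups.values()]
    out: dict[str, float] = {}
    if len(arrays) >= 2:
        out["anova_p"] = float(stats.f_oneway(*arrays)[1])
        out["welch_t_p"] = float(stats.ttest_ind(arrays[0], arrays[1], equal_var=False)[1])
    return out
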