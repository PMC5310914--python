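"""Trinucleotide mutation classes and per-sample spectrum matrices.

A polarized SNP is classified by its ancestral base, the two flanking
reference bases, and the derived base — one of 96 canonical classes once
reverse-complement pairs are merged so that the ancestral base is always a
pyrimidine (C or T). Class labels follow the ``ACG>T`` convention: the
ancestral trinucleotide followed by the derived middle base. Contexts are
read 5'->3' on the reference strand; because each class is collapsed with
its reverse complement, the resulting 96-class partition is identical under
either strand-reading convention.

Per-sample count matrices ``C`` (96 x n_samples) are built for a chosen
derived-allele-count stratum — e.g. f2 ("doubletons": exactly two derived
copies in the whole sample, either one homozygote, counted twice, or two
heterozygotes, counted once each). Intensities ``X`` are counts normalized
either by each sample's ATA>C count (the most common class) or by each
sample's total.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, PYRIMIDINES, complement
from .io import Reference, VariantPanel

logger = logging.getLogger(__name__)

__all__ = [
    "MutationClass",
    "classify_variant",
    "enumerate_classes",
    "parse_class_label",
    "SignatureDefinition",
    "SIGNATURE_1",
    "SIGNATURE_2",
    "SpectrumCounts",
    "IntensityMatrix",
    "count_spectrum",
    "normalize",
    "signature_proportion",
    "group_z",
    "sharing_proportion",
]

# Substitution types in the conventional (COSMIC-style) order.
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = (
    ("C", "A"),
    ("C", "G"),
    ("C", "T"),
    ("T", "A"),
    ("T", "C"),
    ("T", "G"),
)


@dataclass(frozen=True, order=True)
class MutationClass:
    """A canonical pyrimidine-centered trinucleotide substitution."""

    left: str
    ancestral: str
    right: str
    derived: str

    def __post_init__(self) -> None:
        for b in (self.left, self.ancestral, self.right, self.derived):
            if b not in BASES:
                raise ValueError(f"invalid base {b!r} in mutation class")
        if self.ancestral not in PYRIMIDINES:
            raise ValueError(
                f"class {self.label} not canonical: ancestral base must be C or T"
            )
        if self.derived == self.ancestral:
            raise ValueError("derived base equals ancestral base")

    @property
    def context(self) -> str:
        return self.left + self.ancestral + self.right

    @property
    def label(self) -> str:
        return f"{self.context}>{self.derived}"

    @property
    def is_cpg(self) -> bool:
        """True when the ancestral pyrimidine sits in a CpG dinucleotide."""
        return self.ancestral == "C" and self.right == "G"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def classify_variant(left: str, ancestral: str, right: str, derived: str) -> MutationClass:
    """Map a polarized SNP with its flanking bases to its canonical class.

    Purine-ancestral inputs are folded through the reverse complement of the
    full context (and of the derived base).
    """
    for b in (left, ancestral, right, derived):
        if b not in BASES:
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if derived == ancestral:
        raise ValueError("derived base equals ancestral base")
    if ancestral in PYRIMIDINES:
        return MutationClass(left, ancestral, right, derived)
    return MutationClass(
        complement(right), complement(ancestral), complement(left), complement(derived)
    )


def enumerate_classes() -> list[MutationClass]:
    """The 96 canonical classes: 6 substitution types x 16 flank pairs,
    substitution-major, then left flank, then right flank (A<C<G<T)."""
    return [
        MutationClass(l, anc, r, der)
        for anc, der in SUBSTITUTION_TYPES
        for l in BASES
        for r in BASES
    ]


CLASSES: tuple[MutationClass, ...] = tuple(enumerate_classes())
CLASS_LABELS: tuple[str, ...] = tuple(c.label for c in CLASSES)
CLASS_INDEX: dict[MutationClass, int] = {c: i for i, c in enumerate(CLASSES)}
LABEL_INDEX: dict[str, int] = {c.label: i for i, c in enumerate(CLASSES)}

ATA_C_INDEX = LABEL_INDEX["ATA>C"]


def parse_class_label(label: str) -> MutationClass:
    """Parse an ``ACG>T`` style label (canonicalizing if needed)."""
    try:
        context, derived = label.split(">")
        left, anc, right = context
    except ValueError:
        raise ValueError(f"malformed class label {label!r}") from None
    return classify_variant(left, anc, right, derived)


def expand_class_patterns(patterns: Iterable[str]) -> frozenset[MutationClass]:
    """Expand labels which may use N as a wildcard flank (e.g. ``NCG>T``)."""
    out: set[MutationClass] = set()
    for pat in patterns:
        context, derived = pat.split(">")
        lefts = BASES if context[0] == "N" else context[0]
        rights = BASES if context[2] == "N" else context[2]
        deriveds = BASES if derived == "N" else derived
        for l in lefts:
            for r in rights:
                for d in deriveds:
                    if d != context[1]:
                        out.add(classify_variant(l, context[1], r, d))
    return frozenset(out)


@dataclass(frozen=True)
class SignatureDefinition:
    """A named set of mutation classes (e.g. the TCC>T-type signature)."""

    name: str
    classes: frozenset[MutationClass]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("signature must contain at least one class")

    @classmethod
    def from_patterns(cls, name: str, patterns: Iterable[str]) -> "SignatureDefinition":
        return cls(name, expand_class_patterns(patterns))

    @property
    def indices(self) -> np.ndarray:
        return np.array(sorted(CLASS_INDEX[c] for c in self.classes), dtype=int)


#: The West-Eurasian-enriched signature: TCT>T, TCC>T, CCC>T and ACC>T.
SIGNATURE_1 = SignatureDefinition.from_patterns(
    "signature_1", ["TCT>T", "TCC>T", "CCC>T", "ACC>T"]
)
#: The CpG deamination signature: NCG>T for any flanking N.
SIGNATURE_2 = SignatureDefinition.from_patterns("signature_2", ["NCG>T"])


# ---------------------------------------------------------------------------
# Spectrum construction
# ---------------------------------------------------------------------------

Stratum = str | int | tuple[int, int]


def _stratum_bounds(stratum: Stratum, n_chromosomes: int) -> tuple[int, int]:
    """Resolve a stratum selector to an inclusive derived-count range.

    Accepts "f1"/"f2"/"f3"..., a bare integer count, "per_genome" (all
    segregating frequencies), or an explicit (lo, hi) range.
    """
    if isinstance(stratum, tuple):
        lo, hi = stratum
    elif isinstance(stratum, int):
        lo = hi = stratum
    elif stratum == "per_genome":
        lo, hi = 1, n_chromosomes - 1
    elif isinstance(stratum, str) and stratum.startswith("f"):
        lo = hi = int(stratum[1:])
    else:
        raise ValueError(f"unrecognized stratum {stratum!r}")
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid stratum range ({lo}, {hi})")
    return lo, hi


@dataclass
class ClassifiedVariant:
    """A panel variant that survived polarization and context lookup."""

    index: int
    mclass: MutationClass
    flipped: bool  # True when the ancestral pyrimidine lies on the - strand
    derived_counts: np.ndarray  # per-sample derived-allele counts
    total_derived: int


def iter_classified_variants(
    panel: VariantPanel, reference: Reference, skipped: Counter | None = None
) -> Iterator[ClassifiedVariant]:
    """Yield classified, polarized variants; tally skip reasons.

    Records are dropped (with a logged reason) when the ancestral-allele
    annotation is not a confident uppercase base, matches neither allele
    (triallelic history), or the position lacks flanking context.
    """
    if skipped is None:
        skipped = Counter()
    var = panel.variants
    for i, (chrom, pos, ref, alt, aa) in enumerate(
        zip(var["chrom"], var["pos"], var["ref"], var["alt"], var["aa"])
    ):
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            skipped["not_snp"] += 1
            continue
        if aa not in BASES:  # lowercase or ambiguous: not confidently assigned
            skipped["aa_not_confident"] += 1
            continue
        if aa == ref:
            derived = alt
            geno = panel.genotypes[i]
            counts = np.where(geno >= 0, geno, 0).astype(np.int64)
        elif aa == alt:
            derived = ref
            geno = panel.genotypes[i]
            counts = np.where(geno >= 0, 2 - geno, 0).astype(np.int64)
        else:
            skipped["aa_matches_neither_allele"] += 1
            continue
        context = reference.context(chrom, pos)
        if context is None:
            skipped["no_flanking_context"] += 1
            logger.debug("variant at %s:%d at sequence edge, skipped", chrom, pos)
            continue
        left, mid, right = context
        if any(b not in BASES for b in (left, mid, right)):
            skipped["ambiguous_context"] += 1
            continue
        total = int(counts.sum())
        if total == 0:
            skipped["no_derived_alleles"] += 1
            continue
        try:
            mclass = classify_variant(left, aa, right, derived)
        except ValueError:
            skipped["unclassifiable"] += 1
            continue
        yield ClassifiedVariant(i, mclass, aa not in PYRIMIDINES, counts, total)


@dataclass
class SpectrumCounts:
    """Per-sample mutation counts C (96 x n_samples) for one stratum."""

    counts: np.ndarray
    f_stratum: Stratum
    samples: pd.DataFrame
    skipped: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != 96:
            raise ValueError("spectrum must have 96 class rows")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(CLASS_LABELS), columns=list(self.samples["sample"])
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="class")


@dataclass
class IntensityMatrix:
    """Normalized intensities X (96 x n_samples)."""

    values: np.ndarray
    normalization: str
    samples: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(CLASS_LABELS), columns=list(self.samples["sample"])
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="class")


def count_spectrum(
    panel: VariantPanel, reference: Reference, stratum: Stratum = "f2"
) -> SpectrumCounts:
    """Tally per-sample class counts for variants in a derived-count stratum.

    The derived-allele count is computed jointly over all samples (ignoring
    population labels); a homozygous-derived genotype contributes two counts
    and a heterozygous one. Fixed-derived sites are never counted as
    segregating.
    """
    lo, hi = _stratum_bounds(stratum, 2 * panel.n_samples)
    counts = np.zeros((96, panel.n_samples), dtype=np.int64)
    skipped: Counter[str] = Counter(panel.skipped_records)
    for cv in iter_classified_variants(panel, reference, skipped):
        if not lo <= cv.total_derived <= hi or cv.total_derived >= 2 * panel.n_samples:
            continue
        counts[CLASS_INDEX[cv.mclass]] += cv.derived_counts
    return SpectrumCounts(counts, stratum, panel.samples.copy(), skipped)


def normalize(counts: SpectrumCounts, mode: str = "ata_c") -> IntensityMatrix:
    """Normalize counts to intensities.

    ``ata_c``: divide each sample's counts by its ATA>C count (the ATA>C row
    becomes identically 1). ``total``: divide by each sample's total count
    (columns sum to 1).
    """
    C = counts.counts.astype(float)
    if mode == "ata_c":
        denom = C[ATA_C_INDEX]
    elif mode == "total":
        denom = C.sum(axis=0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        names = [counts.samples["sample"].iloc[j] for j in bad]
        raise ValueError(
            f"zero {'ATA>C count' if mode == 'ata_c' else 'total count'} for "
            f"sample(s): {', '.join(map(str, names))}"
        )
    return IntensityMatrix(C / denom, mode, counts.samples.copy())


def signature_proportion(
    counts: SpectrumCounts, sig: SignatureDefinition
) -> pd.Series:
    """Per-sample fraction of counted mutations falling in a signature's
    classes. Samples with zero total are reported as NaN (flagged missing)."""
    totals = counts.counts.sum(axis=0).astype(float)
    in_sig = counts.counts[sig.indices].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, in_sig / np.where(totals > 0, totals, 1), np.nan)
    missing = np.flatnonzero(totals == 0)
    if missing.size:
        logger.warning(
            "%d sample(s) with zero total counts flagged missing", missing.size
        )
    return pd.Series(props, index=list(counts.samples["sample"]), name=sig.name)


def group_z(
    proportions: Sequence[float] | pd.Series,
    group_a: Sequence[int] | np.ndarray,
    group_b: Sequence[int] | np.ndarray,
) -> float:
    """Two-sample Z on per-individual proportions with unpooled (Welch)
    variance: (mean_a - mean_b) / sqrt(var_a/n_a + var_b/n_b)."""
    vals = np.asarray(proportions, dtype=float)
    a = vals[np.asarray(group_a, dtype=int)]
    b = vals[np.asarray(group_b, dtype=int)]
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
    if se2 == 0:
        raise ValueError("degenerate groups: zero variance in both")
    return float((a.mean() - b.mean()) / np.sqrt(se2))


def sharing_proportion(
    panel: VariantPanel,
    reference: Reference,
    split: tuple[Sequence[int], Sequence[int]],
    sig: SignatureDefinition,
    stratum: Stratum = "f2",
) -> tuple[float, float]:
    """Fraction of stratum variants carried on both sides of a sample split,
    for the signature's classes (p_sig) and for all classes (p_all).

    A variant is "shared" when at least one derived copy falls on each side.
    """
    idx_a = np.asarray(split[0], dtype=int)
    idx_b = np.asarray(split[1], dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both sides of the split must be non-empty")
    if set(idx_a) & set(idx_b):
        raise ValueError("split sides overlap")
    lo, hi = _stratum_bounds(stratum, 2 * panel.n_samples)
    sig_idx = set(sig.indices.tolist())
    n_all = n_all_shared = n_sig = n_sig_shared = 0
    for cv in iter_classified_variants(panel, reference):
        if not lo <= cv.total_derived <= hi or cv.total_derived >= 2 * panel.n_samples:
            continue
        shared = cv.derived_counts[idx_a].sum() > 0 and cv.derived_counts[idx_b].sum() > 0
        n_all += 1
        n_all_shared += shared
        if CLASS_INDEX[cv.mclass] in sig_idx:
            n_sig += 1
            n_sig_shared += shared
    if n_all == 0:
        raise ValueError("no variants in stratum")
    p_all = n_all_shared / n_all
    p_sig = n_sig_shared / n_sig if n_sig else float("nan")
    return p_sig, p_all
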