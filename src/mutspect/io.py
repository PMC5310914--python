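"""Containers and file I/O for reference sequences and variant panels.

The in-memory containers are deliberately light: a reference is a mapping of
chromosome name to sequence string, and a variant panel is a pandas DataFrame
of biallelic SNP records plus an integer genotype matrix (derived-allele
counts are computed downstream from the ancestral-allele annotation).

On disk the standard formats are used throughout: FASTA for the reference
(read back via :mod:`pyfaidx`), VCF 4.2 with an ``AA`` INFO tag for panels
(read back via :mod:`pysam`), TSV for sample metadata.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from ._seq import BASES, PYRIMIDINES, reverse_complement

__all__ = [
    "Reference",
    "VariantPanel",
    "read_fasta",
    "read_vcf",
    "read_metadata",
    "write_metadata",
]


@dataclass
class Reference:
    """A reference genome held in memory as plain strings."""

    sequences: dict[str, str]

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def context(self, chrom: str, pos: int) -> str | None:
        """Trinucleotide around 1-based ``pos``; None at sequence edges."""
        seq = self.sequences[chrom]
        i = pos - 1
        if i < 1 or i >= len(seq) - 1:
            return None
        return seq[i - 1 : i + 2]

    def trinucleotide_frequencies(self, pseudocount: float = 0.0) -> pd.Series:
        """Relative frequency of the 32 canonical (pyrimidine-centered)
        trinucleotide contexts, collapsing each triplet with its reverse
        complement."""
        contexts = canonical_contexts()
        ctx_index = {c: i for i, c in enumerate(contexts)}
        canon = np.full(64, -1, dtype=np.int64)
        for code in range(64):
            tri = BASES[code // 16] + BASES[(code // 4) % 4] + BASES[code % 4]
            canon[code] = ctx_index[tri if tri[1] in PYRIMIDINES else reverse_complement(tri)]
        lut = np.full(256, -1, dtype=np.int64)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
        vals = np.zeros(32, dtype=float)
        for seq in self.sequences.values():
            if len(seq) < 3:
                continue
            codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            ok = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
            tri = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
            vals += np.bincount(canon[tri[ok]], minlength=32)
        vals += pseudocount
        total = vals.sum()
        if total == 0:
            raise ValueError("reference contains no unambiguous trinucleotides")
        return pd.Series(vals / total, index=contexts, name="frequency")

    def reverse_complemented(self) -> "Reference":
        return Reference({c: reverse_complement(s) for c, s in self.sequences.items()})

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def canonical_contexts() -> list[str]:
    """The 32 pyrimidine-centered trinucleotide contexts, in a fixed order."""
    return [l + m + r for m in "CT" for l in BASES for r in BASES]


def read_fasta(path: str | Path) -> Reference:
    fa = pyfaidx.Fasta(str(path))
    return Reference({name: str(fa[name][:]).upper() for name in fa.keys()})


@dataclass
class VariantPanel:
    """A biallelic SNP panel with per-sample genotypes.

    ``variants`` columns: chrom, pos (1-based), ref, alt, aa (ancestral
    allele as annotated; lowercase means low confidence). ``genotypes`` is an
    (n_variants, n_samples) int8 matrix of ALT-allele counts, -1 for missing.
    ``samples`` carries at least a ``sample`` column; ``population``,
    ``region`` and ``source`` labels are used by grouped analyses.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: pd.DataFrame
    skipped_records: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_names(self) -> list[str]:
        return list(self.samples["sample"])

    def sample_indices(self, names) -> np.ndarray:
        order = {s: i for i, s in enumerate(self.sample_names)}
        try:
            return np.array([order[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample {e.args[0]!r}") from None

    def write_vcf(self, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
        cols = self.sample_names
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            if contig_lengths:
                for chrom, length in contig_lengths.items():
                    fh.write(f"##contig=<ID={chrom},length={length}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cols) + "\n")
            gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
            for i, row in enumerate(self.variants.itertuples(index=False)):
                gts = "\t".join(gt_strings[int(g)] for g in self.genotypes[i])
                fh.write(
                    f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\tAA={row.aa}\tGT\t{gts}\n"
                )


def read_vcf(path: str | Path, samples_meta: pd.DataFrame | None = None) -> VariantPanel:
    """Read a VCF into a :class:`VariantPanel`.

    Only biallelic SNP records with an ``AA`` INFO tag are retained; skipped
    records are tallied by reason. Confidence filtering on the AA case is
    deferred to spectrum counting, so lowercase annotations survive the trip.
    """
    vf = pysam.VariantFile(str(path))
    sample_names = list(vf.header.samples)
    rows = []
    genos = []
    skipped: Counter[str] = Counter()
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped["multiallelic_or_missing_alt"] += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            skipped["not_snp"] += 1
            continue
        aa = rec.info.get("AA")
        if aa is None:
            skipped["no_aa_tag"] += 1
            continue
        g = np.full(len(sample_names), -1, dtype=np.int8)
        for j, s in enumerate(sample_names):
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                continue
            g[j] = sum(alleles)
        rows.append((rec.chrom, rec.pos, ref, alt, str(aa)))
        genos.append(g)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "aa"])
    genotypes = (
        np.vstack(genos) if genos else np.zeros((0, len(sample_names)), dtype=np.int8)
    )
    if samples_meta is None:
        samples_meta = pd.DataFrame({"sample": sample_names})
    else:
        samples_meta = samples_meta.set_index("sample").loc[sample_names].reset_index()
    return VariantPanel(variants, genotypes, samples_meta, skipped)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
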