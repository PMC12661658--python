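"""Codon-level utilities: translation, reverse translation and
synonymous-site bookkeeping under the standard genetic code."""

from __future__ import annotations

import functools

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"


@functools.lru_cache(maxsize=None)
def codon_to_aa() -> dict[str, str]:
    """Map sense codons to one-letter residues; stop codons map to '*'."""
    table = CodonTable.unambiguous_dna_by_id[1]
    out = dict(table.forward_table)
    for stop in table.stop_codons:
        out[stop] = "*"
    return out


@functools.lru_cache(maxsize=None)
def aa_to_codons() -> dict[str, tuple[str, ...]]:
    out: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa().items():
        out.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in out.items()}


def translate(cds: str) -> str:
    """Translate a CDS; raises on length not divisible by 3 or internal stop."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    if "*" in aa[:-1] or (aa.endswith("*") and "*" in aa[:-1]):
        raise ValueError("internal stop codon in CDS")
    return aa.rstrip("*")


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate a protein, drawing a synonymous codon uniformly per site."""
    lookup = aa_to_codons()
    codons = []
    for aa in protein:
        choices = lookup[aa]
        codons.append(choices[rng.integers(len(choices))])
    return "".join(codons)


def synonymous_alternatives(codon: str) -> list[tuple[int, str]]:
    """Single-nucleotide changes of ``codon`` that preserve the encoded residue.

    Returns (position-in-codon, replacement-codon) pairs.
    """
    aa = codon_to_aa()[codon]
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if codon_to_aa()[alt] == aa:
                out.append((pos, alt))
    return out


@functools.lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Nei-Gojobori synonymous site count of one codon.

    Each codon position contributes the fraction of its three possible
    nucleotide changes that are synonymous; changes to stop codons count
    as nonsynonymous.
    """
    aa = codon_to_aa()[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if codon_to_aa()[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


def synonymous_sites(cds: str) -> float:
    """Total Nei-Gojobori synonymous sites of a CDS (stop codon excluded)."""
    codons = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    if codons and codon_to_aa()[codons[-1]] == "*":
        codons = codons[:-1]
    return float(sum(synonymous_site_fraction(c) for c in codons))
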