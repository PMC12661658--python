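"""Seeded synthetic CLE-like peptide families with planted ground truth.

The generator emulates the structural features of a fast-evolving small
signalling-peptide family: precursors made of a hydrophobic signal segment,
a variable domain and a C-terminal 12-residue functional motif whose
substitutions dominate between-clade divergence; paralog pairs produced by
gene duplication followed by asymmetric erosion of a shared conserved
noncoding promoter block; dodecapeptide collections drawn from a
fielded/coupled Potts distribution; and pooled CRISPR sequencing
experiments with segregating, wild-type-like and mutant-like populations.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aa, codons
from .potts import PottsModel


class ConfigurationError(ValueError):
    """Raised for degenerate or inconsistent simulation configurations."""


# Default root dodecapeptide: the mature CLV3 peptide motif.
ROOT_MOTIF = "RTVPSGPDPLHH"
# Fixed hydrophobic-rich signal-segment prefix (no signal-peptide
# prediction is emulated; annotation filtering is out of scope here).
SIGNAL_SEGMENT = "MASSKALLFLALFLLLSLTPSAHA"

DISRUPTIVE_CONSEQUENCES = frozenset({"frameshift", "stop_gain", "motif_disrupting"})

THREEPOOL_COLUMNS = [
    "chrom", "pos", "gene_id", "consequence",
    "af_seg", "af_wt", "af_mut",
    "depth_seg", "depth_wt", "depth_mut",
]


@dataclass
class GeneRecord:
    """One synthetic family member with its planted-truth labels."""

    gene_id: str
    species: str
    precursor: str
    dodecapeptide: str
    cds: str
    promoter: str
    clade_truth: str
    paralog_group_truth: str | None = None

    def validate(self) -> None:
        if len(self.dodecapeptide) != 12:
            raise ValueError(f"{self.gene_id}: dodecapeptide length != 12")
        prot = codons.translate(self.cds)
        if prot != self.precursor:
            raise ValueError(f"{self.gene_id}: CDS does not encode precursor")
        if self.precursor[-12:] != self.dodecapeptide:
            raise ValueError(f"{self.gene_id}: motif is not the precursor C-terminus")


@dataclass
class FamilySimConfig:
    """Study conditions for one simulated family."""

    n_clades: int = 6
    genes_per_clade: int = 20
    motif_divergence: float = 0.25   # substitutions / site / clade split
    promoter_length: int = 1000
    cns_block: tuple[int, int] = (300, 200)   # (start, length)
    erosion_asymmetry: float = 0.5   # fraction of the block lost per paralog side
    duplication_events: int = 6
    variable_length: int = 45
    # duplicates evolve their motif under relaxed selection: a multiple of
    # the within-clade rate
    paralog_rate_factor: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_clades <= 0 or self.genes_per_clade <= 0:
            raise ConfigurationError("n_clades and genes_per_clade must be positive")
        if not (0.0 <= self.motif_divergence <= 1.0):
            raise ConfigurationError("motif_divergence must be in [0, 1]")
        if not (0.0 <= self.erosion_asymmetry <= 1.0):
            raise ConfigurationError("erosion_asymmetry must be in [0, 1]")
        start, length = self.cns_block
        if start < 0 or length <= 0 or start + length > self.promoter_length:
            raise ConfigurationError("cns_block must lie within the promoter")
        if self.duplication_events < 0:
            raise ConfigurationError("duplication_events must be >= 0")
        if self.paralog_rate_factor < 0:
            raise ConfigurationError("paralog_rate_factor must be >= 0")
        if self.variable_length < 0:
            raise ConfigurationError("variable_length must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside generated data."""

    clade_partition: dict[str, str] = field(default_factory=dict)
    paralog_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    generating_model: PottsModel | None = None
    causal_genes: set[str] = field(default_factory=set)
    # Retained conserved-block interval per paralog-pair member, in
    # ancestral-block coordinates [start, end).
    cns_retained: dict[str, tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sequence evolution helpers


def _blosum_proposal_matrix(temperature: float = 2.0) -> np.ndarray:
    """Row-stochastic substitution proposal biased by BLOSUM62 exchangeability."""
    b = aa.blosum62()
    w = np.exp(b / temperature)
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def _mutate_protein(seq: np.ndarray, rate: float, rng: np.random.Generator,
                    proposal: np.ndarray) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = rng.choice(aa.A, p=proposal[out[i]])
    return out


def _random_protein(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, aa.A, size=length)


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(codons.NUCLEOTIDES), size=length))


def _reencode_changed(cds: str, protein: str, rng: np.random.Generator) -> str:
    """Update a CDS to encode ``protein``, re-drawing codons only at
    changed residues so codon usage is inherited elsewhere."""
    codon_list = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    table = codons.codon_to_aa()
    for i, aa_char in enumerate(protein):
        if table[codon_list[i]] != aa_char:
            choices = codons.aa_to_codons()[aa_char]
            codon_list[i] = choices[rng.integers(len(choices))]
    return "".join(codon_list)


def _evolve_clades(n_clades: int, motif0: np.ndarray, var0: np.ndarray,
                   cds0: str, rate: float, rng: np.random.Generator,
                   proposal: np.ndarray,
                   syn_per_branch: float = 3.0
                   ) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Balanced binary clade tree; per-branch substitutions at ``rate``.

    The ancestral CDS descends the same tree: changed residues are
    re-encoded and a Poisson number of synonymous changes is planted per
    branch, so codon usage carries phylogenetic signal.
    """
    def branch(motif, var, cds):
        m = _mutate_protein(motif, rate, rng, proposal)
        v = _mutate_protein(var, rate, rng, proposal)
        prot = SIGNAL_SEGMENT + aa.decode(v) + aa.decode(m)
        c = _reencode_changed(cds, prot, rng)
        c, _ = _apply_synonymous_changes(c, int(rng.poisson(syn_per_branch)), rng)
        return m, v, c

    def rec(n: int, motif: np.ndarray, var: np.ndarray, cds: str):
        if n == 1:
            return [(motif, var, cds)]
        left_n = (n + 1) // 2
        return rec(left_n, *branch(motif, var, cds)) + \
            rec(n - left_n, *branch(motif, var, cds))

    return rec(n_clades, motif0, var0, cds0)


def _apply_synonymous_changes(cds: str, n_changes: int,
                              rng: np.random.Generator) -> tuple[str, int]:
    """Plant up to ``n_changes`` synonymous single-nucleotide changes in
    distinct codons; returns the altered CDS and the realized count."""
    codon_list = [cds[i: i + 3] for i in range(0, len(cds), 3)]
    eligible = [i for i, c in enumerate(codon_list) if codons.synonymous_alternatives(c)]
    k = min(n_changes, len(eligible))
    chosen = rng.choice(len(eligible), size=k, replace=False)
    for j in chosen:
        idx = eligible[j]
        alts = codons.synonymous_alternatives(codon_list[idx])
        _, alt = alts[rng.integers(len(alts))]
        codon_list[idx] = alt
    return "".join(codon_list), k


# ---------------------------------------------------------------------------
# family generator


def generate_family(config: FamilySimConfig) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Simulate a peptide gene family with nested clades and paralog pairs.

    Clades descend a balanced binary tree from an ancestral precursor;
    each branch applies BLOSUM62-biased substitutions to the motif and the
    variable domain at ``motif_divergence`` per site.  Within a clade,
    genes diverge at one tenth of that rate.  ``duplication_events``
    paralog pairs are created by copying a gene, lightly mutating its
    protein, planting synonymous CDS changes (recorded as ``dS_truth``)
    and eroding complementary ends of the shared conserved promoter block
    by ``erosion_asymmetry`` of its length on each side.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    proposal = _blosum_proposal_matrix()

    motif0 = aa.encode(ROOT_MOTIF)
    var0 = _random_protein(config.variable_length, rng)
    root_prot = SIGNAL_SEGMENT + aa.decode(var0) + aa.decode(motif0)
    cds0 = codons.reverse_translate(root_prot, rng)
    within_rate = config.motif_divergence / 10.0

    clade_ancestors = _evolve_clades(
        config.n_clades, motif0, var0, cds0, config.motif_divergence, rng, proposal
    )
    cns_seq = _random_dna(config.cns_block[1], rng)
    species_pool = ["sp1", "sp2", "sp3"]

    genes: list[GeneRecord] = []
    truth = SyntheticTruth()
    for c, (cm, cv, ccds) in enumerate(clade_ancestors):
        for g in range(config.genes_per_clade):
            motif = _mutate_protein(cm, within_rate, rng, proposal)
            var = _mutate_protein(cv, within_rate, rng, proposal)
            precursor = SIGNAL_SEGMENT + aa.decode(var) + aa.decode(motif)
            cds = _reencode_changed(ccds, precursor, rng)
            cds, _ = _apply_synonymous_changes(cds, int(rng.poisson(1.5)), rng)
            start, length = config.cns_block
            promoter = _random_dna(config.promoter_length, rng)
            block = _mutate_dna(cns_seq, 0.05, rng)
            promoter = promoter[:start] + block + promoter[start + length:]
            gid = f"g{c:02d}_{g:03d}"
            rec = GeneRecord(
                gene_id=gid,
                species=species_pool[(c * config.genes_per_clade + g) % len(species_pool)],
                precursor=precursor,
                dodecapeptide=aa.decode(motif),
                cds=cds,
                promoter=promoter,
                clade_truth=f"clade{c}",
            )
            genes.append(rec)
            truth.clade_partition[gid] = rec.clade_truth

    _plant_duplications(genes, truth, config, rng, proposal)
    for rec in genes:
        rec.validate()
    return genes, truth


def _mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alts = [nt for nt in codons.NUCLEOTIDES if nt != chars[i]]
        chars[i] = alts[rng.integers(3)]
    return "".join(chars)


def _plant_duplications(genes: list[GeneRecord], truth: SyntheticTruth,
                        config: FamilySimConfig, rng: np.random.Generator,
                        proposal: np.ndarray) -> None:
    if config.duplication_events == 0:
        return
    n_events = min(config.duplication_events, len(genes))
    sources = rng.choice(len(genes), size=n_events, replace=False)
    start, length = config.cns_block
    e = config.erosion_asymmetry
    keep_a = int(round((1.0 - e) * length))   # side A keeps the leading part
    keep_b = length - int(round(e * length))  # side B keeps the trailing part
    within_rate = config.motif_divergence / 10.0
    dup_motif_rate = min(1.0, within_rate * config.paralog_rate_factor)

    for k, src_idx in enumerate(sorted(sources)):
        src = genes[src_idx]
        group = f"pg{k}"
        motif = _mutate_protein(aa.encode(src.dodecapeptide), dup_motif_rate,
                                rng, proposal)
        var_len = len(src.precursor) - len(SIGNAL_SEGMENT) - 12
        var = _mutate_protein(
            aa.encode(src.precursor[len(SIGNAL_SEGMENT): len(SIGNAL_SEGMENT) + var_len]),
            within_rate, rng, proposal,
        )
        precursor = SIGNAL_SEGMENT + aa.decode(var) + aa.decode(motif)

        # CDS: inherit the parent's codons, re-encode changed residues,
        # then plant synonymous changes whose count is the dS oracle.
        codon_list = [src.cds[i: i + 3] for i in range(0, len(src.cds), 3)]
        for i, aa_char in enumerate(precursor):
            if codons.codon_to_aa()[codon_list[i]] != aa_char:
                choices = codons.aa_to_codons()[aa_char]
                codon_list[i] = choices[rng.integers(len(choices))]
        cds = "".join(codon_list)
        n_syn = int(rng.integers(2, 9))
        cds, realized = _apply_synonymous_changes(cds, n_syn, rng)

        # complementary promoter-block erosion: parent keeps the leading
        # (1-e) fraction, duplicate keeps the trailing (1-e) fraction.
        parent_promoter = (
            src.promoter[: start + keep_a] + src.promoter[start + length:]
        )
        dup_promoter = (
            src.promoter[:start] + src.promoter[start + (length - keep_b):]
        )
        dup_id = src.gene_id + "d"
        dup = GeneRecord(
            gene_id=dup_id,
            species=src.species,
            precursor=precursor,
            dodecapeptide=aa.decode(motif),
            cds=cds,
            promoter=dup_promoter,
            clade_truth=src.clade_truth,
            paralog_group_truth=group,
        )
        src.promoter = parent_promoter
        src.paralog_group_truth = group
        genes.append(dup)
        truth.clade_partition[dup_id] = dup.clade_truth
        s_sites = 0.5 * (codons.synonymous_sites(src.cds) + codons.synonymous_sites(cds))
        truth.paralog_pairs.append((src.gene_id, dup_id, realized / s_sites))
        truth.cns_retained[src.gene_id] = (0, keep_a)
        truth.cns_retained[dup_id] = (length - keep_b, length)


# ---------------------------------------------------------------------------
# Potts sampler


def sample_potts_sequences(model: PottsModel, n: int, burn_in: int = 200,
                           seed: int = 0) -> list[str]:
    """Draw ``n`` motif sequences from a Potts distribution by Gibbs sampling.

    Runs ``n`` independent chains (one per output sequence) for
    ``burn_in`` full site sweeps from uniform-random starts.  Higher
    statistical energy means higher probability.
    """
    if n == 0:
        return []
    if n < 0:
        raise ValueError("n must be >= 0")
    model.check_shapes()
    rng = np.random.default_rng(seed)
    L, A = model.L, model.A
    state = rng.integers(0, A, size=(n, L))
    for _ in range(burn_in):
        for i in range(L):
            logits = np.broadcast_to(model.h[i], (n, A)).copy()
            for j in range(L):
                if j == i:
                    continue
                logits += model.J[i, j][:, state[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n)
            state[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return [aa.decode(row) for row in state]


# ---------------------------------------------------------------------------
# three-pool CRISPR experiment


def generate_three_pool_experiment(
    genes: list[GeneRecord],
    causal: set[str],
    n_plants_per_pool: int = 30,
    depth: int = 100,
    seed: int = 0,
    noiseless: bool = False,
    n_offtargets: int = 30,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate pooled bulk sequencing of three phenotype-sorted populations.

    Every gene is targeted with one knockout variant (disruptive
    consequence).  Causal-gene knockouts are homozygous in the mutant-like
    pool, absent in the wild-type-like pool and segregate at allele
    frequency 1/2 in the middle pool; non-causal knockouts segregate at a
    phenotype-independent frequency shared across pools.  Observed allele
    fractions are binomial draws at the given read depth unless
    ``noiseless`` is set.
    """
    targeted = {g.gene_id for g in genes}
    if not causal <= targeted:
        raise ValueError("causal genes must be a subset of the targeted gene set")
    if not noiseless and depth <= 0:
        raise ValueError("read depth must be positive")
    rng = np.random.default_rng(seed)
    consequences = sorted(DISRUPTIVE_CONSEQUENCES)

    def pool_freq(allele_freq: float) -> float:
        if noiseless:
            return allele_freq
        n_alleles = 2 * n_plants_per_pool
        return rng.binomial(n_alleles, allele_freq) / n_alleles

    def observed(f: float) -> float:
        if noiseless:
            return f
        return rng.binomial(depth, f) / depth

    rows = []
    pos = 10_000
    for i, g in enumerate(sorted(genes, key=lambda r: r.gene_id)):
        if g.gene_id in causal:
            f_mut, f_wt, f_seg = 1.0, 0.0, pool_freq(0.5)
        else:
            f0 = rng.uniform(0.25, 0.75)
            f_mut, f_wt, f_seg = pool_freq(f0), pool_freq(f0), pool_freq(f0)
        cons = consequences[int(rng.integers(len(consequences)))]
        rows.append((
            f"chr{1 + i % 12}", pos, g.gene_id, cons,
            observed(f_seg), observed(f_wt), observed(f_mut),
            depth, depth, depth,
        ))
        pos += 1000
        # occasional in-phase silent variant at the same locus
        if rng.random() < 0.3:
            rows.append((
                f"chr{1 + i % 12}", pos, g.gene_id, "synonymous",
                observed(f_seg), observed(f_wt), observed(f_mut),
                depth, depth, depth,
            ))
            pos += 7

    for _ in range(n_offtargets):
        f0 = rng.uniform(0.0, 1.0)
        rows.append((
            f"chr{1 + int(rng.integers(12))}", pos, None, "intergenic",
            observed(pool_freq(f0)), observed(pool_freq(f0)), observed(pool_freq(f0)),
            depth, depth, depth,
        ))
        pos += 997

    table = pd.DataFrame(rows, columns=THREEPOOL_COLUMNS)
    truth = SyntheticTruth(
        clade_partition={g.gene_id: g.clade_truth for g in genes},
        causal_genes=set(causal),
    )
    return table, truth


# ---------------------------------------------------------------------------
# site conservation


def generate_site_conservation(L: int, n_conserved: int, seed: int = 0) -> list[float]:
    """Per-site conservation values with ``n_conserved`` positions planted
    above the 0.6 calling threshold and the remainder below it."""
    if n_conserved > L:
        raise ValueError("n_conserved must be <= L")
    rng = np.random.default_rng(seed)
    values = np.concatenate([
        rng.uniform(0.65, 1.0, size=n_conserved),
        rng.uniform(0.0, 0.55, size=L - n_conserved),
    ])
    rng.shuffle(values)
    return values.tolist()
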