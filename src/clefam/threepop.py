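"""Three-population CRISPR bulk-sequencing candidate-gene analysis.

A segregating population is compared against two phenotype-fixed pools
(wild-type-like and mutant-like).  Each gene's mutational index (MI) is
the allele fraction of its strongest disruptive variant in the
mutant-like pool, paired with the same variant's wild-type-pool fraction;
genes falling in the bottom-right corner (high MI in the mutant pool, low
in the wild-type pool, intermediate in the segregating pool) are called
as phenotype candidates.  Candidate sets are then tested for clustering
within the promoter-similarity network by permutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .paralogs import PromoterNetwork
from .synthdata import DISRUPTIVE_CONSEQUENCES


@dataclass
class GeneMI:
    """Per-gene mutational-index summary across the three pools."""

    gene_id: str
    mi_mut: float | None
    mi_wt: float | None
    af_seg: float | None
    seg_support: bool
    is_offtarget: bool = False


def mutational_index(table: pd.DataFrame, tau_hi: float = 0.8,
                     tau_lo: float = 0.2,
                     disruptive: frozenset[str] = DISRUPTIVE_CONSEQUENCES
                     ) -> list[GeneMI]:
    """Summarize each gene's disruptive variants into a mutational index.

    mi_mut is the maximum mutant-pool allele fraction over the gene's
    disruptive-consequence variants; mi_wt and the segregating fraction
    are read from that same variant (ties broken by position).
    seg_support requires the segregating fraction strictly inside
    (tau_lo, tau_hi).  Genes with no disruptive variant are emitted with
    null indices; off-target rows (null gene_id) are aggregated under a
    per-locus synthetic id and flagged.
    """
    if table.empty:
        raise ValueError("empty variant table")
    df = table.copy()
    off = df["gene_id"].isna()
    df.loc[off, "gene_id"] = [
        f"offtarget_{c}_{p}" for c, p in zip(df.loc[off, "chrom"], df.loc[off, "pos"])
    ]
    out: list[GeneMI] = []
    for gid, grp in df.groupby("gene_id", sort=True):
        is_off = bool(off[grp.index].iloc[0])
        hits = grp[grp["consequence"].isin(disruptive)].sort_values(["af_mut", "pos"],
                                                                    ascending=[False, True])
        if hits.empty:
            out.append(GeneMI(gene_id=str(gid), mi_mut=None, mi_wt=None,
                              af_seg=None, seg_support=False, is_offtarget=is_off))
            continue
        top = hits.iloc[0]
        seg = float(top["af_seg"])
        out.append(GeneMI(
            gene_id=str(gid),
            mi_mut=float(top["af_mut"]),
            mi_wt=float(top["af_wt"]),
            af_seg=seg,
            seg_support=bool(tau_lo < seg < tau_hi),
            is_offtarget=is_off,
        ))
    return out


def call_candidates(mis: list[GeneMI], tau_hi: float = 0.8,
                    tau_lo: float = 0.2) -> set[str]:
    """Bottom-right candidate calling: mi_mut >= tau_hi, mi_wt <= tau_lo
    and segregating support; off-target loci and genes without a
    disruptive variant are never candidates."""
    out = set()
    for m in mis:
        if m.is_offtarget or m.mi_mut is None:
            continue
        if m.mi_mut >= tau_hi and m.mi_wt <= tau_lo and m.seg_support:
            out.add(m.gene_id)
    return out


def promoter_cluster_test(candidates: set[str], network: PromoterNetwork,
                          n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for promoter-network clustering of candidates.

    The statistic is the mean pairwise promoter similarity among the
    candidate genes (absent edges count 0); the null redraws same-size
    node sets uniformly from the network.  p uses the
    (1 + #{null >= observed}) / (n_perm + 1) convention.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate genes")
    nodes = sorted(network.nodes)
    missing = candidates - set(nodes)
    if missing:
        raise ValueError(f"candidates not in network: {sorted(missing)}")

    def stat(members: list[str]) -> float:
        sims = [network.similarity(u, v)
                for u, v in itertools.combinations(members, 2)]
        return float(np.mean(sims))

    obs = stat(sorted(candidates))
    rng = np.random.default_rng(seed)
    k = len(candidates)
    exceed = 0
    for _ in range(n_perm):
        draw = rng.choice(len(nodes), size=k, replace=False)
        if stat([nodes[i] for i in draw]) >= obs - 1e-15:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def filter_expression_samples(tpm: pd.DataFrame, mapping_rates: dict[str, float],
                              replicate_groups: dict[str, list[str]],
                              min_mapping: float = 0.5,
                              min_correlation: float = 0.75) -> set[str]:
    """Expression-sample quality filter.

    Drops samples whose uniquely-mapped read rate is <= ``min_mapping``,
    then, within each replicate group, computes pairwise Spearman
    correlations on log2(TPM + 1) and drops samples whose median
    correlation to the other replicates is <= ``min_correlation``.
    ``tpm`` is samples x genes.
    """
    if tpm.empty:
        raise ValueError("empty expression table")
    retained = {s for s in tpm.index if mapping_rates.get(s, 0.0) > min_mapping}
    logt = np.log2(tpm + 1.0)
    for _, members in sorted(replicate_groups.items()):
        group = [s for s in members if s in retained]
        if len(group) < 2:
            continue
        sub = logt.loc[group]
        rho = scipy.stats.spearmanr(sub.T.values).statistic
        if np.ndim(rho) == 0:   # two-sample group: scalar correlation
            rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        for i, s in enumerate(group):
            others = np.delete(rho[i], i)
            if float(np.median(others)) <= min_correlation:
                retained.discard(s)
    return retained
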