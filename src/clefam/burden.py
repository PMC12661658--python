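"""Synonymous distances and the paralog mutational-burden comparison.

Duplication age between coding sequences is proxied by dS, the number of
synonymous substitutions per synonymous site, computed by Nei-Gojobori
(1986) counting with pathway averaging for multi-hit codons and the
Jukes-Cantor multiple-hit correction.  Motif burden is the accumulated
deleterious Potts-energy loss of a gene relative to its clade reference,
and the paralog-versus-homolog comparison regresses burden on dS and
paralogy with a within-stratum permutation test on the paralogy flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from . import codons
from .potts import PottsModel, mutational_effect

log = logging.getLogger(__name__)


@dataclass
class DsResult:
    ds: float | None
    p_s: float
    syn_sites: float
    saturated: bool


@dataclass
class BurdenRecord:
    gene_id: str
    reference_id: str
    burden: float
    ds: float
    is_paralog_pair: bool


# ---------------------------------------------------------------------------
# Nei-Gojobori dS


def _codon_path_counts(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts for one
    codon pair.

    Minimal mutational pathways (orderings of the differing positions) are
    enumerated; pathways passing through a stop codon are excluded, and
    each surviving pathway contributes its per-step synonymous and
    nonsynonymous counts with equal weight.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    table = codons.codon_to_aa()
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if table[nxt] == "*":
                ok = False
                break
            if table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        # all pathways via stops: fall back to counting every step as
        # nonsynonymous (degenerate, essentially never hit with real CDS)
        return 0.0, float(len(diff))
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


def synonymous_distance(cds_a: str, cds_b: str) -> DsResult:
    """Nei-Gojobori dS with Jukes-Cantor correction.

    Synonymous site counts are averaged between the two sequences;
    p_s >= 3/4 is outside the correction domain and sets the saturated
    flag with an undefined dS.  Symmetric in its arguments.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences must have equal length")
    if len(cds_a) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codons.translate(cds_a)
    codons.translate(cds_b)
    S = 0.5 * (codons.synonymous_sites(cds_a) + codons.synonymous_sites(cds_b))
    sd_total = 0.0
    table = codons.codon_to_aa()
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i: i + 3], cds_b[i: i + 3]
        if table[ca] == "*" or table[cb] == "*":
            continue
        sd, _ = _codon_path_counts(ca, cb)
        sd_total += sd
    p_s = sd_total / S if S > 0 else 0.0
    if p_s >= 0.75:
        return DsResult(ds=None, p_s=p_s, syn_sites=S, saturated=True)
    ds = -0.75 * float(np.log(1.0 - 4.0 * p_s / 3.0))
    return DsResult(ds=ds, p_s=p_s, syn_sites=S, saturated=False)


# ---------------------------------------------------------------------------
# burden


def burden_score(model: PottsModel, seq: str, reference: str) -> float:
    """Accumulated deleterious energy loss of ``seq`` relative to the
    reference motif: sum over differing positions of max(0, -dE), where
    dE is the single-substitution effect reference -> seq residue."""
    if len(seq) != len(reference):
        raise ValueError("sequence and reference must have equal length")
    total = 0.0
    for i, (r, s) in enumerate(zip(reference, seq)):
        if r != s:
            de = mutational_effect(model, reference, i + 1, s)
            total += max(0.0, -de)
    return total


def clade_consensus(motifs: list[str]) -> str:
    """Column-majority consensus motif (ties broken alphabetically)."""
    if not motifs:
        raise ValueError("empty motif list")
    L = len(motifs[0])
    out = []
    for i in range(L):
        counts: dict[str, int] = {}
        for m in motifs:
            counts[m[i]] = counts.get(m[i], 0) + 1
        best = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == best))
    return "".join(out)


# ---------------------------------------------------------------------------
# burden test


def _ols_flag_coefficient(burden: np.ndarray, ds: np.ndarray,
                          flag: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(ds), ds, flag.astype(float)])
    coef, *_ = np.linalg.lstsq(X, burden, rcond=None)
    return float(coef[2])


def paralog_burden_test(records: list[BurdenRecord], n_perm: int = 999,
                        seed: int = 0, n_strata: int = 4):
    """Burden-versus-paralogy effect controlling for duplication age.

    Fits burden ~ dS + is_paralog by least squares; significance of the
    paralogy coefficient comes from permuting the flag within dS strata
    (quantile bins, default quartiles), two-sided, with the
    (1 + #extreme) / (n_perm + 1) convention so p is never zero.  Strata
    containing a single class are dropped with a warning; an error is
    raised if nothing remains.
    """
    burden = np.array([r.burden for r in records], dtype=float)
    ds = np.array([r.ds for r in records], dtype=float)
    flag = np.array([r.is_paralog_pair for r in records], dtype=bool)
    if flag.all() or not flag.any():
        raise ValueError("need both paralog and non-paralog records")

    edges = np.quantile(ds, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(edges, ds, side="right") - 1, 0, n_strata - 1)
    keep = np.zeros(len(records), dtype=bool)
    for s in np.unique(strata):
        mask = strata == s
        if flag[mask].all() or not flag[mask].any():
            log.warning("dS stratum %d has a single class; dropped", s)
            continue
        keep |= mask
    if not keep.any():
        raise ValueError("all dS strata degenerate; cannot permute")
    burden, ds, flag, strata = burden[keep], ds[keep], flag[keep], strata[keep]

    if np.all(burden == 0.0):
        return 0.0, 1.0

    obs = _ols_flag_coefficient(burden, ds, flag)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = flag.copy()
        for s in np.unique(strata):
            mask = strata == s
            perm[mask] = rng.permutation(perm[mask])
        if abs(_ols_flag_coefficient(burden, ds, perm)) >= abs(obs) - 1e-15:
            extreme += 1
    p = (1 + extreme) / (n_perm + 1)
    return obs, p
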