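"""End-to-end pipeline orchestration.

Chains similarity network -> embedding -> hierarchy -> paralog groups ->
Potts model -> burden (-> three-population analysis when pools are
available) under one seeded configuration, writing every artifact and a
checksum manifest into a run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import embed as embed_mod
from . import hierarchy as hier_mod
from . import io as io_mod
from . import paralogs as paralogs_mod
from . import potts as potts_mod
from . import simnet as simnet_mod
from . import synthdata
from . import threepop as threepop_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unknown keys are rejected on load."""

    seed: int = 0
    outdir: str = "clefam_run"
    input_dir: str | None = None        # read gene records instead of simulating

    # family simulation
    n_clades: int = 6
    genes_per_clade: int = 20
    motif_divergence: float = 0.25
    duplication_events: int = 6
    erosion_asymmetry: float = 0.5

    # similarity network
    min_weight: float = 0.0
    top_k: int = 500

    # embedding
    dims: int = 128
    walk_length: int = 80
    walks_per_node: int = 20
    context_window: int = 10
    knn_k: int = 10
    large_scale_walks: bool = False

    # hierarchy
    n_resolutions: int = 6
    prune_alpha: float = 0.05
    prune_n_perm: int = 99
    rf_estimators: int = 50

    # paralog grouping
    promoter_k: int = 12
    sim_seed_threshold: float = 0.5

    # burden
    burden_n_perm: int = 499

    # three-pool
    run_threepop: bool = True
    n_causal: int = 3
    pool_depth: int = 100
    tau_hi: float = 0.8
    tau_lo: float = 0.2
    threepop_n_perm: int = 999

    # stage toggles
    run_embed: bool = True
    run_hierarchy: bool = True
    run_paralogs: bool = True
    run_potts: bool = True
    run_burden: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key = value config file; unknown keys are errors."""
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, value = (x.strip() for x in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, known[key].type)
        return cls(**kwargs)


def _coerce(value: str, typ) -> object:
    t = str(typ)
    if "bool" in t:
        return value.lower() in {"1", "true", "yes"}
    if "int" in t:
        return int(value)
    if "float" in t:
        return float(value)
    return value


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages and return the run directory.

    Every stochastic stage derives its seed from the global one; a rerun
    with the same configuration reproduces every artifact bit-for-bit.
    The manifest lists each output with its SHA-256 checksum.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    timings: dict[str, float] = {}
    rng = np.random.default_rng(config.seed)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s done in %.2fs", name, timings[name])
            return result
        return wrap

    # --- genes ----------------------------------------------------------
    def _genes():
        if config.input_dir:
            genes = io_mod.read_gene_records(config.input_dir)
            truth = None
        else:
            fam = synthdata.FamilySimConfig(
                n_clades=config.n_clades,
                genes_per_clade=config.genes_per_clade,
                motif_divergence=config.motif_divergence,
                duplication_events=config.duplication_events,
                erosion_asymmetry=config.erosion_asymmetry,
                seed=config.seed,
            )
            genes, truth = synthdata.generate_family(fam)
        artifacts.extend(io_mod.write_gene_records(genes, outdir))
        return genes, truth

    genes, truth = stage("genes")(_genes)

    # --- similarity network --------------------------------------------
    def _net():
        g = simnet_mod.build_graph(genes, min_weight=config.min_weight)
        g = simnet_mod.prune_top_k(g, config.top_k)
        p = outdir / "network.tsv"
        g.to_tsv(p)
        artifacts.append(p)
        return g

    graph = stage("simnet")(_net)

    emb = knn = None
    if config.run_embed:
        def _embed():
            wc = (embed_mod.WalkConfig.large_scale(seed=config.seed)
                  if config.large_scale_walks else
                  embed_mod.WalkConfig(
                      walk_length=config.walk_length,
                      walks_per_node=config.walks_per_node,
                      context_window=config.context_window,
                      seed=config.seed,
                  ))
            walks = embed_mod.random_walks(graph, wc)
            e = embed_mod.embed_walks(walks, dims=config.dims,
                                      context_window=wc.context_window)
            k = embed_mod.knn_graph(e, min(config.knn_k, len(e.ids) - 1))
            coords = embed_mod.project_2d(e)
            ep = outdir / "embedding.tsv"
            pd.DataFrame(e.vectors, index=e.ids).to_csv(ep, sep="\t", header=False)
            cp = outdir / "coords2d.tsv"
            pd.DataFrame(
                [(g, x, y) for g, (x, y) in sorted(coords.items())],
                columns=["gene_id", "x", "y"],
            ).to_csv(cp, sep="\t", index=False)
            kp = outdir / "knn.tsv"
            k.to_tsv(kp)
            artifacts.extend([ep, cp, kp])
            return e, k

        emb, knn = stage("embed")(_embed)

    if config.run_hierarchy:
        def _tree():
            ladder = hier_mod.default_resolution_ladder(graph, config.n_resolutions)
            parts = hier_mod.multires_communities(graph, ladder, seed=config.seed)
            tree = hier_mod.reconcile_tree(parts)
            motifs = {g.gene_id: g.dodecapeptide for g in genes}
            tree = hier_mod.prune_sisters_rf(
                tree, motifs, n_perm=config.prune_n_perm,
                alpha=config.prune_alpha, seed=config.seed,
                n_estimators=config.rf_estimators,
            )
            np_path = outdir / "hierarchy.nwk"
            io_mod.write_newick(tree.to_newick(), np_path)
            jp = outdir / "hierarchy.json"
            jp.write_text(tree.to_json())
            artifacts.extend([np_path, jp])
            return tree

        stage("hierarchy")(_tree)

    if config.run_paralogs and knn is not None:
        def _groups():
            net = paralogs_mod.build_promoter_network(genes, k=config.promoter_k)
            np_ = outdir / "promoter_network.tsv"
            net.graph.to_tsv(np_)
            groups = paralogs_mod.assign_paralog_groups(
                genes, knn, net, sim_seed_threshold=config.sim_seed_threshold)
            gp = outdir / "paralog_groups.tsv"
            pd.DataFrame(sorted(groups.items()), columns=["gene_id", "group"]
                         ).to_csv(gp, sep="\t", index=False)
            artifacts.extend([np_, gp])
            return net, groups

        promoter_net, _ = stage("paralogs")(_groups)
    else:
        promoter_net = None

    model = None
    if config.run_potts:
        def _potts():
            msa = [g.dodecapeptide for g in genes]
            m = potts_mod.fit_potts(msa)
            mp = outdir / "potts_model.json"
            m.to_json(mp)
            wt = genes[0].dodecapeptide
            land = potts_mod.mutational_landscape(m, wt)
            rows = []
            for i in range(m.L):
                for b, mut_aa in enumerate(potts_mod.aa.ALPHABET):
                    rows.append((i + 1, wt[i], mut_aa, land.effects[i, b]))
            lp = outdir / "landscape.tsv"
            pd.DataFrame(rows, columns=["position", "wt_aa", "mut_aa", "delta_E"]
                         ).to_csv(lp, sep="\t", index=False)
            resid, _, rep = potts_mod.residualize_blosum(land)
            sn = potts_mod.sneath_correlation(resid, wt)
            vp = outdir / "potts_validation.json"
            vp.write_text(json.dumps({
                "blosum": dataclasses.asdict(rep),
                "sneath": dataclasses.asdict(sn),
            }, sort_keys=True))
            artifacts.extend([mp, lp, vp])
            return m

        model = stage("potts")(_potts)

    if config.run_burden and model is not None and truth is not None:
        def _burden():
            records = _burden_records(genes, truth, model, rng)
            bp = outdir / "burden_records.tsv"
            pd.DataFrame(
                [(r.gene_id, r.reference_id, r.burden, r.ds, r.is_paralog_pair)
                 for r in records],
                columns=["gene_id", "reference_id", "burden", "dS", "is_paralog"],
            ).to_csv(bp, sep="\t", index=False)
            est, p = burden_mod.paralog_burden_test(
                records, n_perm=config.burden_n_perm, seed=config.seed)
            rp = outdir / "burden_test.json"
            rp.write_text(json.dumps({"effect": est, "p_value": p}, sort_keys=True))
            artifacts.extend([bp, rp])

        stage("burden")(_burden)

    if config.run_threepop and truth is not None and promoter_net is not None:
        def _threepop():
            ids = sorted(g.gene_id for g in genes)
            causal = set(
                np.random.default_rng(config.seed + 17).choice(
                    ids, size=min(config.n_causal, len(ids)), replace=False)
            )
            table, ptruth = synthdata.generate_three_pool_experiment(
                genes, causal, depth=config.pool_depth, seed=config.seed + 29)
            tp = outdir / "threepool.tsv"
            io_mod.write_threepool(table, tp)
            mis = threepop_mod.mutational_index(table, config.tau_hi, config.tau_lo)
            called = threepop_mod.call_candidates(mis, config.tau_hi, config.tau_lo)
            p = (threepop_mod.promoter_cluster_test(
                    called, promoter_net, n_perm=config.threepop_n_perm,
                    seed=config.seed + 31)
                 if len(called) >= 2 else None)
            rp = outdir / "threepop_report.json"
            rp.write_text(json.dumps({
                "candidates": sorted(called),
                "planted_causal": sorted(ptruth.causal_genes),
                "promoter_cluster_p": p,
            }, sort_keys=True))
            artifacts.extend([tp, rp])

        stage("threepop")(_threepop)

    # timings go in a sidecar, keeping the manifest bit-identical across
    # reruns of the same configuration
    (outdir / "timings.json").write_text(
        json.dumps({k: round(v, 3) for k, v in timings.items()}, sort_keys=True))
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return outdir


def _burden_records(genes, truth, model, rng) -> list:
    """Per-gene burden vs clade consensus, with dS to the paralog partner
    (paralog records) or to a random same-clade gene (background)."""
    by_clade: dict[str, list] = {}
    for g in genes:
        by_clade.setdefault(g.clade_truth, []).append(g)
    consensus = {c: burden_mod.clade_consensus([g.dodecapeptide for g in members])
                 for c, members in by_clade.items()}
    by_id = {g.gene_id: g for g in genes}
    paralog_members = {a for a, b, _ in truth.paralog_pairs} | {
        b for a, b, _ in truth.paralog_pairs}

    records = []
    for a, b, _ in truth.paralog_pairs:
        gb = by_id[b]
        ds = burden_mod.synonymous_distance(by_id[a].cds, gb.cds)
        if ds.saturated:
            continue
        records.append(burden_mod.BurdenRecord(
            gene_id=b, reference_id=f"consensus_{gb.clade_truth}",
            burden=burden_mod.burden_score(model, gb.dodecapeptide,
                                           consensus[gb.clade_truth]),
            ds=ds.ds, is_paralog_pair=True))
    for g in genes:
        if g.gene_id in paralog_members:
            continue
        others = [o for o in by_clade[g.clade_truth]
                  if o.gene_id != g.gene_id and o.gene_id not in paralog_members]
        if not others:
            continue
        partner = others[int(rng.integers(len(others)))]
        ds = burden_mod.synonymous_distance(g.cds, partner.cds)
        if ds.saturated:
            continue
        records.append(burden_mod.BurdenRecord(
            gene_id=g.gene_id, reference_id=f"consensus_{g.clade_truth}",
            burden=burden_mod.burden_score(model, g.dodecapeptide,
                                           consensus[g.clade_truth]),
            ds=ds.ds, is_paralog_pair=False))
    return records
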