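"""File formats: FASTA, TSV tables, Newick, and variant-table parsing.

All artifacts round-trip: read(write(x)) == x for gene sets, edge lists,
trees, Potts-model containers and three-pool variant tables.  Malformed
records raise errors carrying the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthdata import THREEPOOL_COLUMNS, GeneRecord


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


# ---------------------------------------------------------------------------
# gene-record sets


def write_gene_records(genes: list[GeneRecord], outdir: str | Path) -> list[Path]:
    """Write precursors/CDS/promoters as FASTA plus a metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, attr in [("precursors", "precursor"), ("cds", "cds"),
                       ("promoters", "promoter")]:
        p = outdir / f"{name}.fasta"
        write_fasta({g.gene_id: getattr(g, attr) for g in genes}, p)
        paths.append(p)
    meta = pd.DataFrame(
        [(g.gene_id, g.species, g.clade_truth, g.paralog_group_truth or "")
         for g in genes],
        columns=["gene_id", "species", "clade_truth", "paralog_group_truth"],
    )
    mp = outdir / "genes.tsv"
    meta.to_csv(mp, sep="\t", index=False)
    paths.append(mp)
    return paths


def read_gene_records(indir: str | Path) -> list[GeneRecord]:
    indir = Path(indir)
    precursors = read_fasta(indir / "precursors.fasta")
    cds = read_fasta(indir / "cds.fasta")
    promoters = read_fasta(indir / "promoters.fasta")
    meta = pd.read_csv(indir / "genes.tsv", sep="\t", keep_default_na=False)
    out = []
    for row in meta.itertuples(index=False):
        gid = str(row.gene_id)
        out.append(GeneRecord(
            gene_id=gid,
            species=str(row.species),
            precursor=precursors[gid],
            dodecapeptide=precursors[gid][-12:],
            cds=cds[gid],
            promoter=promoters[gid],
            clade_truth=str(row.clade_truth),
            paralog_group_truth=str(row.paralog_group_truth) or None,
        ))
    return out


# ---------------------------------------------------------------------------
# Newick


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:   # dendropy raises assorted parse errors
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# three-pool variant tables


def write_threepool(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_threepool(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in THREEPOOL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        for col in ("af_seg", "af_wt", "af_mut"):
            v = getattr(row, col)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{path}:{ln}: {col}={v} outside [0, 1]")
        for col in ("depth_seg", "depth_wt", "depth_mut"):
            if getattr(row, col) <= 0:
                raise ValueError(f"{path}:{ln}: non-positive {col}")
    df["gene_id"] = df["gene_id"].astype(object).where(df["gene_id"].notna(), None)
    return df[THREEPOOL_COLUMNS]


def parse_vcf_threepool(path: str | Path) -> pd.DataFrame:
    """Parse a minimal VCF with three samples (seg, wt, mut) carrying AD
    fields into the three-pool table layout.  Gene assignment is read from
    a GENE= INFO key when present."""
    rows = []
    with open(path) as fh:
        samples: list[str] = []
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                if len(samples) != 3:
                    raise ValueError(f"{path}:{ln}: need exactly 3 sample columns")
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{ln}: truncated record")
            chrom, pos, _, _, _, _, _, info, fmt = parts[:9]
            keys = fmt.split(":")
            if "AD" not in keys:
                raise ValueError(f"{path}:{ln}: no AD field")
            ad_i = keys.index("AD")
            afs, depths = [], []
            for cell in parts[9:12]:
                ad = cell.split(":")[ad_i]
                ref_n, alt_n = (int(x) for x in ad.split(",")[:2])
                depth = ref_n + alt_n
                if depth <= 0:
                    raise ValueError(f"{path}:{ln}: zero depth")
                afs.append(alt_n / depth)
                depths.append(depth)
            info_d = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            rows.append((chrom, int(pos), info_d.get("GENE"),
                         info_d.get("CSQ", "unknown"),
                         afs[0], afs[1], afs[2], depths[0], depths[1], depths[2]))
    return pd.DataFrame(rows, columns=THREEPOOL_COLUMNS)
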