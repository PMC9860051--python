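"""Readers and writers for the pipeline's file formats.

Gene tables travel as flat TSV (the primary interchange format) or GFF3;
domain hits use the HMMER3 ``--domtblout`` dialect (whitespace-delimited,
``#`` comments); search hits use BLAST tabular with the standard 12 columns
plus ``qcovs`` and a subject-family column. Annotations, loci, intensity and
spot tables are plain TSV; genome truth is JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import pandas as pd

from .core import Gene
from .synthetic import GenomeTruth, PlantedPUL

GENE_TABLE_COLUMNS = [
    "gene_id",
    "contig_id",
    "order_index",
    "start",
    "end",
    "strand",
    "locus_tag",
]


# ---------------------------------------------------------------- gene tables
def write_gene_table(genes, path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "contig_id": g.contig_id,
                "order_index": g.order_index,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "locus_tag": g.locus_tag or "",
            }
            for g in genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"locus_tag": str}, keep_default_na=False)
    return [
        Gene(
            contig_id=row["contig_id"],
            order_index=int(row["order_index"]),
            gene_id=row["gene_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            locus_tag=row["locus_tag"] or None,
        )
        for _, row in df.iterrows()
    ]


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.locus_tag:
                attrs += f";locus_tag={g.locus_tag}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "pulcascade",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list:
    """Load protein-coding features from GFF3; order indices are assigned by
    start coordinate within each contig."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    per_contig: dict = {}
    for feat in db.features_of_type("CDS"):
        per_contig.setdefault(feat.seqid, []).append(feat)
    genes = []
    for contig in sorted(per_contig):
        feats = sorted(per_contig[contig], key=lambda f: f.start)
        for idx, f in enumerate(feats):
            locus = f.attributes.get("locus_tag", [None])[0]
            genes.append(
                Gene(
                    contig_id=contig,
                    order_index=idx,
                    gene_id=f.attributes.get("ID", [f.id])[0],
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    locus_tag=locus,
                )
            )
    return genes


def write_protein_fasta(genes, path) -> None:
    """Placeholder protein sequences (synthetic; sequence content is not
    modeled, only identifiers and lengths matter)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for g in genes:
        length = max(1, (g.end - g.start + 1) // 3)
        records.append(
            SeqRecord(Seq("M" + "A" * (length - 1)), id=g.gene_id, description="")
        )
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------- domain tables
_DOMTBL_PROFILE_LEN = 300


def write_domtbl(hits: pd.DataFrame, path) -> None:
    """Write domain hits in the HMMER3 ``--domtblout`` dialect (hmmscan
    orientation: the profile is the target, the protein the query)."""
    with open(path, "w") as fh:
        fh.write(
            "# target name        accession   tlen query name           "
            "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
            "i-Evalue  score  bias  from    to  from    to  from    to  "
            "acc description of target\n#\n"
        )
        for _, row in hits.iterrows():
            tlen = _DOMTBL_PROFILE_LEN
            hmm_to = max(1, round(row["profile_coverage"] * tlen))
            env_start = int(row.get("env_start", 1))
            env_end = int(row.get("env_end", env_start + row["alignment_length"] - 1))
            fields = [
                str(row["profile_name"]),
                "-",
                str(tlen),
                str(row["protein_id"]),
                "-",
                "450",
                f"{row['e_value']:.3g}",
                "100.0",
                "0.0",
                "1",
                "1",
                f"{row['e_value']:.3g}",
                f"{row['e_value']:.3g}",
                "100.0",
                "0.0",
                "1",
                str(hmm_to),
                str(env_start),
                str(env_end),
                str(env_start),
                str(env_end),
                "0.90",
                "-",
            ]
            fh.write(" ".join(fields) + "\n")


def read_domtbl(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(maxsplit=22)
            if len(fields) < 22:
                raise ValueError(f"{path}: malformed domtbl row {lineno}")
            tlen = int(fields[2])
            hmm_from, hmm_to = int(fields[15]), int(fields[16])
            env_from, env_to = int(fields[19]), int(fields[20])
            rows.append(
                {
                    "protein_id": fields[3],
                    "profile_name": fields[0],
                    "e_value": float(fields[12]),  # i-Evalue (per domain)
                    "alignment_length": env_to - env_from + 1,
                    "profile_coverage": (hmm_to - hmm_from + 1) / tlen,
                    "env_start": env_from,
                    "env_end": env_to,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "profile_name",
            "e_value",
            "alignment_length",
            "profile_coverage",
            "env_start",
            "env_end",
        ],
    )


# ------------------------------------------------------------- search tables
BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qcovs",
    "sfamily",
]


def write_search_table(hits: pd.DataFrame, path) -> None:
    """BLAST tabular: 12 standard columns + ``qcovs`` + subject family."""
    with open(path, "w") as fh:
        for _, row in hits.iterrows():
            fields = [
                str(row["query_id"]),
                str(row["subject_id"]),
                f"{row['percent_identity']:.1f}",
                "200",
                "0",
                "0",
                "1",
                "200",
                "1",
                "200",
                f"{row['e_value']:.3g}",
                "250.0",
                f"{row['query_coverage']:.1f}",
                str(row["subject_family"]),
            ]
            fh.write("\t".join(fields) + "\n")


def read_search_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=BLAST_COLUMNS, comment="#")
    return pd.DataFrame(
        {
            "query_id": df["qseqid"],
            "subject_id": df["sseqid"],
            "subject_family": df["sfamily"],
            "percent_identity": df["pident"],
            "query_coverage": df["qcovs"],
            "e_value": df["evalue"],
        }
    )


# ---------------------------------------------------------------- annotations
def write_annotations(annotations: dict, path) -> None:
    rows = []
    for gene_id in sorted(annotations):
        for call in sorted(annotations[gene_id], key=lambda c: c.label):
            rows.append(
                {
                    "gene_id": gene_id,
                    "label": call.label,
                    "evidence": ";".join(sorted(call.evidence)),
                }
            )
    pd.DataFrame(rows, columns=["gene_id", "label", "evidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path, genes=None) -> dict:
    from .core import AnnotationCall

    df = pd.read_csv(path, sep="\t")
    annotations: dict = (
        {g.gene_id: set() for g in genes} if genes is not None else {}
    )
    for _, row in df.iterrows():
        annotations.setdefault(row["gene_id"], set()).add(
            AnnotationCall(
                row["gene_id"], row["label"], frozenset(row["evidence"].split(";"))
            )
        )
    return {k: frozenset(v) for k, v in annotations.items()}


# ------------------------------------------------------------------ PUL table
def puls_to_frame(puls) -> pd.DataFrame:
    rows = []
    for pul in puls:
        susc, susd = pul.anchor
        rows.append(
            {
                "contig_id": pul.contig_id,
                "span_start": pul.span[0],
                "span_end": pul.span[1],
                "susc_gene": susc.gene_id,
                "susd_gene": susd.gene_id,
                "n_genes": pul.n_genes,
                "n_anchors": len(pul.anchors),
                "families": ";".join(sorted(pul.family_set)),
                "cazyme_genes": ";".join(f"{g}:{f}" for g, f in pul.cazyme_calls),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "span_start",
            "span_end",
            "susc_gene",
            "susd_gene",
            "n_genes",
            "n_anchors",
            "families",
            "cazyme_genes",
        ],
    )


def write_puls(puls, path) -> None:
    puls_to_frame(puls).to_csv(path, sep="\t", index=False)


def write_puls_json(puls, path) -> None:
    """Full per-locus provenance (anchors, gene list, merge history)."""
    payload = [
        {
            "contig_id": p.contig_id,
            "span": list(p.span),
            "anchors": [[susc.gene_id, susd.gene_id] for susc, susd in p.anchors],
            "genes": [g.gene_id for g in p.genes],
            "cazyme_calls": [list(c) for c in p.cazyme_calls],
            "family_set": sorted(p.family_set),
            "provenance": p.provenance,
        }
        for p in puls
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------- intensity / spot tables
def write_intensity(matrix: pd.DataFrame, meta: pd.DataFrame, matrix_path, meta_path) -> None:
    matrix.to_csv(matrix_path, sep="\t")
    meta.to_csv(meta_path, sep="\t")


def read_intensity(matrix_path, meta_path):
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return matrix, meta


def write_spots(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, sep="\t", index=False)


def read_spots(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ----------------------------------------------------------------- truth JSON
def write_truth(truth: GenomeTruth, path) -> None:
    payload = {
        "genes": [asdict(g) for g in truth.genes],
        "true_labels": truth.true_labels,
        "profiles": truth.profiles,
        "planted_puls": [asdict(p) for p in truth.planted_puls],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> GenomeTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GenomeTruth(
        genes=[Gene(**g) for g in payload["genes"]],
        true_labels=payload["true_labels"],
        profiles=payload["profiles"],
        planted_puls=[PlantedPUL(**p) for p in payload["planted_puls"]],
    )
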