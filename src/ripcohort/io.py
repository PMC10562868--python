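"""Readers and writers for the pipeline's plain-text formats.

Counts/metadata/property tables are TSV; sequences are FASTA with record IDs
``<gene>|utr5`` / ``<gene>|cds`` / ``<gene>|utr3``; annotations are GFF3
(1-based inclusive, features five_prime_UTR/CDS/three_prime_UTR on a
per-gene seqid); gene sets are GMT; trees are Newick.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SyntheticTruth, TranscriptAnnotation


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_table(df: pd.DataFrame, path, index_label="gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


# ---------------------------------------------------------------------------
# FASTA / GFF3


def write_annotation_fasta(annotation: TranscriptAnnotation, path) -> None:
    records = []
    for g in annotation.genes:
        for region, seqs in (("utr5", annotation.utr5), ("cds", annotation.cds),
                             ("utr3", annotation.utr3)):
            seq = seqs[g]
            if seq:
                records.append(SeqRecord(Seq(seq), id=f"{g}|{region}", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_annotation_fasta(path) -> dict[str, dict[str, str]]:
    """Returns {region: {gene: sequence}} for regions utr5/cds/utr3."""
    out = {"utr5": {}, "cds": {}, "utr3": {}}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, region = rec.id.partition("|")
        if region not in out:
            raise ValueError(f"unknown region {region!r} in FASTA record {rec.id}")
        out[region][gene] = str(rec.seq).upper()
    return out


_GFF_FEATURES = (("five_prime_UTR", "utr5_len"), ("CDS", "cds_len"),
                 ("three_prime_UTR", "utr3_len"))


def write_annotation_gff3(annotation: TranscriptAnnotation, path) -> None:
    """Transcript-coordinate GFF3: one seqid per gene, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            row = annotation.lengths.loc[g]
            pos = 1
            for feature, col in _GFF_FEATURES:
                length = int(row[col])
                if length == 0:
                    continue
                end = pos + length - 1
                fh.write(f"{g}\tripcohort\t{feature}\t{pos}\t{end}\t.\t+\t.\t"
                         f"ID={g}.{feature};Parent={g}\n")
                pos = end + 1


def read_annotation_gff3(path, fasta_path=None) -> TranscriptAnnotation:
    """Rebuild a :class:`TranscriptAnnotation` from GFF3 (+ optional FASTA)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    lengths: dict[str, dict[str, int]] = {}
    col_of = {feat: col for feat, col in _GFF_FEATURES}
    for feat in db.all_features():
        gene = feat.seqid
        lengths.setdefault(gene, {"utr5_len": 0, "cds_len": 0, "utr3_len": 0})
        if feat.featuretype in col_of:
            lengths[gene][col_of[feat.featuretype]] += feat.end - feat.start + 1
    table = pd.DataFrame.from_dict(lengths, orient="index").sort_index()
    seqs = {"utr5": {}, "cds": {}, "utr3": {}}
    if fasta_path is not None:
        seqs = read_annotation_fasta(fasta_path)
    return TranscriptAnnotation(lengths=table, utr5=seqs["utr5"], cds=seqs["cds"],
                                utr3=seqs["utr3"])


# ---------------------------------------------------------------------------
# truth tables / gene sets


def write_truth(truth: SyntheticTruth, outdir) -> None:
    outdir = Path(outdir)
    truth.cluster_labels.to_frame().to_csv(outdir / "truth_labels.tsv", sep="\t",
                                           index_label="gene")
    truth.center_matrix.to_csv(outdir / "truth_centers.tsv", sep="\t")
    truth.gene_lfc.to_csv(outdir / "truth_lfc.tsv", sep="\t", index_label="gene")
    truth.baseline_abundance.to_frame().to_csv(outdir / "truth_baseline.tsv",
                                               sep="\t", index_label="gene")


def write_gmt(sets: dict[str, set], path, description: str = "ripcohort") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_gmt(path) -> dict[str, set]:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def read_term2gene(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=0, names=["term", "gene"])


def write_universe(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))


def read_universe(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
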