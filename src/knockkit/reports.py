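"""Tabular, FASTA and GenBank report writers.

Primer tables emulate the layout of genome-wide knockout primer databases:
one row per gene with the four tailed primers, per-primer core Tm/GC and the
two flank product sizes. All coordinates in reports are 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .assembly import AssemblyResult
from .primer_design import DeletionDesign
from .screening import RestorationAssay, ScreenAssay

_GB_DATE = "01-JAN-2000"  # fixed so outputs are byte-reproducible


def primer_table(designs: Iterable[DeletionDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        row: dict = {
            "gene_id": d.gene_id,
            "contig": d.gene.contig,
            "strand": d.gene.strand,
            "status": d.status,
            "mode": d.flanks.mode,
            "truncated": d.flanks.truncated,
            "deleted_span_bp": d.flanks.deleted_span,
            "marker": d.marker_name,
        }
        for side, pair, reason in (
            ("5", d.pair_5prime, d.reason_5prime),
            ("3", d.pair_3prime, d.reason_3prime),
        ):
            if pair is None:
                row[f"product_{side}_bp"] = pd.NA
                row[f"reason_{side}"] = reason or ""
                continue
            row[f"product_{side}_bp"] = pair.product_length
            row[f"reason_{side}"] = ""
            for role, cand in ((f"{side}F", pair.forward), (f"{side}R", pair.reverse)):
                tailed = (d.tailed_primers or {}).get(role)
                row[role] = tailed.full_seq if tailed else cand.core_seq
                row[f"{role}_core_tm"] = round(cand.tm, 2)
                row[f"{role}_core_gc"] = round(cand.gc, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def screen_table(
    assays: Iterable[tuple[str, Optional[ScreenAssay]]]
) -> pd.DataFrame:
    rows = []
    for gene_id, assay in assays:
        if assay is None:
            rows.append({"gene_id": gene_id, "side": "", "outside_primer": "",
                         "marker_primer": "", "expected_mutant_bp": pd.NA,
                         "expected_wildtype": "none"})
        else:
            rows.append(
                {
                    "gene_id": gene_id,
                    "side": assay.side,
                    "outside_primer": assay.outside_primer,
                    "outside_primer_pos": f"{assay.outside_primer_contig}:"
                                          f"{assay.outside_primer_start + 1}",
                    "marker_primer": assay.marker_primer,
                    "expected_mutant_bp": assay.expected_mutant_product,
                    "expected_wildtype": "none",
                }
            )
    return pd.DataFrame(rows)


def restoration_row(assay: RestorationAssay) -> dict:
    return {
        "gene_id": assay.gene_id,
        "fwd": assay.fwd,
        "rev": assay.rev,
        "expected_restored_bp": assay.expected_restored_product,
        "expected_deletion": "none",
    }


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def plasmid_record(
    design: DeletionDesign, assembly: AssemblyResult, marker_name: str
) -> SeqRecord:
    """GenBank-style record for an assembled knockout plasmid."""
    if not assembly.ok or assembly.plasmid_seq is None:
        raise ValueError("cannot write a failed or linear assembly as a plasmid")
    seq = assembly.plasmid_seq
    rec = SeqRecord(
        Seq(seq),
        id=f"pKO_{design.gene_id}"[:16],
        name=f"pKO_{design.gene_id}"[:16],
        description=f"knockout plasmid for {design.gene_id} ({marker_name} marker)",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "date": _GB_DATE,
        },
    )
    tails = design.tailed_primers
    amp5_len = design.pair_5prime.product_length + 2 * len(tails["5F"].tail)
    amp3_len = design.pair_3prime.product_length + 2 * len(tails["3R"].tail)
    cassette = assembly.cassette_seq or ""
    start5 = seq.find(cassette[:60]) if cassette else -1
    if start5 >= 0:
        k = len(tails["5F"].tail)
        spans = {
            "5' flank amplicon (tailed)": (start5, start5 + amp5_len),
            "marker": (start5 + amp5_len - k, start5 + len(cassette) - amp3_len + k),
            "3' flank amplicon (tailed)": (
                start5 + len(cassette) - amp3_len,
                start5 + len(cassette),
            ),
        }
        for label, (a, b) in spans.items():
            rec.features.append(
                SeqFeature(
                    FeatureLocation(a, min(b, len(seq))),
                    type="misc_feature",
                    qualifiers={"label": [label]},
                )
            )
    for junction in assembly.junction_report:
        rec.features.append(
            SeqFeature(
                FeatureLocation(0, 0),
                type="misc_recomb",
                qualifiers={
                    "label": [
                        f"junction {junction.fragment_a}->{junction.fragment_b} "
                        f"({junction.overlap} nt exact)"
                    ]
                },
            )
        )
    return rec


def write_genbank(record: SeqRecord, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        seqio_write([record], fh, "genbank")


def write_cassette_fasta(
    entries: Iterable[tuple[str, str]], path: str | os.PathLike, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
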