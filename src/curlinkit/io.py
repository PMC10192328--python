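"""File I/O: FASTA sequences, annotation tables, PFMs, reports.

Machine-readable outputs use 0-based half-open coordinates and
tab-separated UTF-8 tables with a header line.
"""

from __future__ import annotations

import json

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mining import CurlinRepeat, SubunitAnnotation
from .motifs import PositionFrequencyMatrix

ANNOTATION_COLUMNS = ("id", "start", "end", "pass", "half",
                      "degenerate_n", "degenerate_q", "insertion")


def read_fasta(path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in records],
        str(path), "fasta",
    )


def write_annotation_tsv(dataset: list[SubunitAnnotation], path) -> None:
    """One row per repeat (0-based half-open coordinates)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for ann in dataset:
            for r in ann.repeats:
                fh.write("\t".join(map(str, (
                    ann.id, r.start, r.end, r.pass_id, int(r.half),
                    int(r.degenerate_n), int(r.degenerate_q), int(r.insertion),
                ))) + "\n")


def write_subunit_tsv(dataset: list[SubunitAnnotation], path) -> None:
    cols = ("id", "length", "n_repeats", "n_strands", "terminal_type",
            "n22_like", "class")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for ann in dataset:
            fh.write("\t".join(map(str, (
                ann.id, ann.length, ann.n_repeats, ann.n_strands,
                ann.terminal_type, int(ann.n22_like),
                ann.class_label or "NA",
            ))) + "\n")


def _repeat_to_dict(r: CurlinRepeat) -> dict:
    return {
        "start": r.start, "end": r.end, "pass": r.pass_id, "half": r.half,
        "degenerate_n": r.degenerate_n, "degenerate_q": r.degenerate_q,
        "insertion": r.insertion,
    }


def annotation_to_dict(ann: SubunitAnnotation) -> dict:
    return {
        "id": ann.id,
        "length": ann.length,
        "n_repeats": ann.n_repeats,
        "n_strands": ann.n_strands,
        "terminal_type": ann.terminal_type,
        "n22_like": ann.n22_like,
        "class": ann.class_label,
        "repeats": [_repeat_to_dict(r) for r in ann.repeats],
    }


def annotation_from_dict(d: dict, sequence: str | None = None) -> SubunitAnnotation:
    repeats = [CurlinRepeat(
        r["start"], r["end"], r["pass"], half=r.get("half", False),
        degenerate_n=r.get("degenerate_n", False),
        degenerate_q=r.get("degenerate_q", False),
        insertion=r.get("insertion", False),
    ) for r in d["repeats"]]
    return SubunitAnnotation(
        id=d["id"], length=d["length"], repeats=repeats,
        n22_like=d.get("n22_like", False), class_label=d.get("class"),
        sequence=sequence,
    )


def write_annotation_json(dataset: list[SubunitAnnotation], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([annotation_to_dict(a) for a in dataset], fh, indent=1)
        fh.write("\n")


def read_annotation_json(path) -> list[SubunitAnnotation]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [annotation_from_dict(d) for d in data]


def write_pfm(pfm: PositionFrequencyMatrix, path_prefix) -> None:
    """Plain-text counts matrix (logo-ready) plus a JSON summary."""
    prefix = str(path_prefix)
    pfm.counts.to_csv(f"{prefix}.counts.tsv", sep="\t")
    with open(f"{prefix}.json", "w", encoding="utf-8") as fh:
        json.dump(pfm.to_dict(), fh, indent=1)
        fh.write("\n")
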