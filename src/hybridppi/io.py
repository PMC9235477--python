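"""Readers and writers for the plain-text formats the tool touches.

Formats: FASTA for sequences (via Biopython), tab-separated edge lists
(``protein_a<TAB>protein_b[<TAB>weight]``, ``#`` comments), labelled
pair tables with an ``id_a/id_b[/label]`` header, GLIDE score tables,
and an HDF5 cache of per-protein embedding matrices.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError
from .training import ExamplePair

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pairs",
    "write_pairs",
    "read_edge_list",
    "write_edge_list",
    "write_score_table",
    "read_score_table",
    "write_glide_targets",
    "save_embeddings",
    "load_embeddings",
]


def read_fasta(path) -> dict:
    """Read FASTA into an id -> uppercased sequence map.

    Ids run up to the first whitespace in the header; duplicate ids and
    empty sequences are rejected by name.
    """
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        seq = str(record.seq).upper()
        if pid in out:
            raise ParseError(f"duplicate sequence id {pid!r}", path=str(path))
        if not seq:
            raise ParseError(f"empty sequence for id {pid!r}", path=str(path))
        out[pid] = seq
    return out


def write_fasta(path, sequences: dict, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="")
        for pid, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# pair tables

PAIR_COLUMNS = ("id_a", "id_b", "label")


def read_pairs(path) -> list:
    """Read a labelled (or unlabelled) pair table into ExamplePairs.

    Expected header: ``id_a<TAB>id_b[<TAB>label]``; labels, when the
    column is present, must be 0 or 1. Errors carry line numbers.
    """
    out: list[ExamplePair] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file (no header)", path=str(path), line=1) from None
        header = [h.strip() for h in header]
        if header[:2] != ["id_a", "id_b"] or header not in (
            ["id_a", "id_b"], ["id_a", "id_b", "label"]
        ):
            raise ParseError(
                f"expected header id_a<TAB>id_b[<TAB>label], got {header}", path=str(path), line=1
            )
        has_label = len(header) == 3
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, got {len(row)}", path=str(path), line=lineno
                )
            id_a, id_b = row[0].strip(), row[1].strip()
            if not id_a or not id_b:
                raise ParseError("empty protein identifier", path=str(path), line=lineno)
            label = None
            if has_label:
                if row[2].strip() not in ("0", "1"):
                    raise ParseError(
                        f"label must be 0 or 1, got {row[2]!r}", path=str(path), line=lineno
                    )
                label = int(row[2])
            try:
                out.append(ExamplePair(id_a=id_a, id_b=id_b, label=label))
            except ValidationError as exc:
                raise ParseError(str(exc), path=str(path), line=lineno) from None
    return out


def write_pairs(path, pairs, with_label: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PAIR_COLUMNS if with_label else PAIR_COLUMNS[:2])
        for ex in pairs:
            if isinstance(ex, ExamplePair):
                row = [ex.id_a, ex.id_b] + ([ex.label] if with_label else [])
            else:
                row = list(ex[:2]) + ([ex[2]] if with_label else [])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# edge lists

def read_edge_list(path) -> list:
    """Read (id, id[, weight]) records; ``#`` lines are comments."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"expected 2 or 3 tab-separated fields, got {len(fields)}",
                    path=str(path), line=lineno,
                )
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ParseError("empty protein identifier", path=str(path), line=lineno)
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ParseError(
                        f"weight not a number: {fields[2]!r}", path=str(path), line=lineno
                    ) from None
                records.append((a, b, w))
            else:
                records.append((a, b, 1.0))
    return records


def write_edge_list(path, net_or_edges, header_comment: str | None = None) -> None:
    edges = net_or_edges.edges() if hasattr(net_or_edges, "edges") else net_or_edges
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for rec in edges:
            a, b, *w = rec
            weight = w[0] if w else 1.0
            fh.write(f"{a}\t{b}\t{weight:g}\n")


# ---------------------------------------------------------------------------
# score tables

def write_score_table(path, pairs, scores, column: str = "glide_score") -> None:
    """TSV ``protein_a<TAB>protein_b<TAB><column>`` with 6 decimals."""
    with open(path, "w") as fh:
        fh.write(f"protein_a\tprotein_b\t{column}\n")
        for (a, b), s in zip(pairs, scores):
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def read_score_table(path) -> tuple[list, np.ndarray]:
    pairs, scores = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_a\tprotein_b\t"):
            raise ParseError("unexpected score-table header", path=str(path), line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError("expected 3 columns", path=str(path), line=lineno)
            try:
                s = float(fields[2])
            except ValueError:
                raise ParseError(
                    f"score not a number: {fields[2]!r}", path=str(path), line=lineno
                ) from None
            pairs.append((fields[0], fields[1]))
            scores.append(s)
    return pairs, np.array(scores)


def write_glide_targets(path, result) -> None:
    """Sidecar TSV for co-supervision targets:
    ``id_a<TAB>id_b<TAB>glide_score<TAB>glide_target`` (NA for pairs
    excluded from the co-supervision term)."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tglide_score\tglide_target\n")
        for ex in result.examples:
            score = "NA" if ex.glide_score is None else f"{ex.glide_score:.6f}"
            target = "NA" if ex.glide_target is None else str(ex.glide_target)
            fh.write(f"{ex.id_a}\t{ex.id_b}\t{score}\t{target}\n")


# ---------------------------------------------------------------------------
# embedding cache

def save_embeddings(path, embeddings: dict) -> None:
    """Persist an id -> (L x d0) matrix map as an HDF5 container."""
    with h5py.File(path, "w") as fh:
        for pid, mat in embeddings.items():
            fh.create_dataset(pid, data=np.asarray(mat, dtype=np.float64))


def load_embeddings(path) -> dict:
    out = {}
    with h5py.File(path, "r") as fh:
        for pid in fh:
            out[pid] = np.asarray(fh[pid])
    return out
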