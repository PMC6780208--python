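"""File formats: FASTA, TSV tables, ELISA matrices, run manifests."""
from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assembly import BindingMatrix
from .detect import ModuleHit
from .synth import TruthRow

HITS_COLUMNS = ["protein_id", "module_class", "start0", "end0",
                "score", "evalue", "type_label"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def hits_to_frame(hits: list[ModuleHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"protein_id": h.protein_id, "module_class": h.module_class,
          "start0": h.start, "end0": h.end, "score": round(h.score, 4),
          "evalue": h.evalue, "type_label": h.type_label} for h in hits],
        columns=HITS_COLUMNS)


def write_hits_tsv(hits: list[ModuleHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth: list[TruthRow], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in truth]).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> list[TruthRow]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [TruthRow(r.protein_id, r.token, int(r.start0), int(r.end0),
                     r.source_class, str(r.type_label)) for r in df.itertuples()]


def read_elisa_tsv(path: str | Path, standard_response: float | None = None) -> BindingMatrix:
    """ELISA matrix TSV: first column dockerin_id, remaining columns cohesins."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dockerin_ids = [str(x) for x in df.index]
    cohesin_ids = [str(c) for c in df.columns]
    raw = df.to_numpy(float).T  # internal layout: rows = cohesins
    return BindingMatrix(cohesin_ids=cohesin_ids, dockerin_ids=dockerin_ids,
                         raw=raw, standard_response=standard_response)


def write_relative_tsv(matrix: BindingMatrix, path: str | Path) -> None:
    if matrix.relative is None:
        raise ValueError("matrix not normalized")
    pd.DataFrame(matrix.relative.T, index=matrix.dockerin_ids,
                 columns=matrix.cohesin_ids).to_csv(path, sep="\t")


def read_annotation_tsv(path: str | Path) -> list[ModuleHit]:
    """User-supplied module annotations (protein_id, token, start, end).

    Lets auxiliary module classes without reference profiles enter the
    pipeline as pre-made hits (score/E-value not applicable, set to 0).
    """
    df = pd.read_csv(path, sep="\t")
    return [ModuleHit(protein_id=str(r.protein_id), module_class=str(r.token),
                      start=int(r.start), end=int(r.end), score=0.0, evalue=0.0)
            for r in df.itertuples()]


def write_pfm_tsv(pfm, path: str | Path) -> None:
    from . import seqs
    pd.DataFrame(pfm.freqs, index=range(1, pfm.length + 1),
                 columns=list(seqs.AA)).to_csv(path, sep="\t",
                                               index_label="position")


def write_signatures_tsv(rows: list[dict], path: str | Path) -> None:
    """Signature rows: protein_id, repeat_index, pos1..pos22 residues."""
    cols = ["protein_id", "repeat_index", "pos1", "pos3", "pos5", "pos9",
            "pos12", "pos10", "pos11", "pos17", "pos18", "pos22"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_manifest(path: str | Path, subcommand: str, params: dict,
                   inputs: list[str], outputs: list[str]) -> None:
    from . import __version__
    manifest = {
        "subcommand": subcommand,
        "parameters": params,
        "inputs": inputs,
        "outputs": outputs,
        "tool_version": __version__,
        "command_line": sys.argv,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
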