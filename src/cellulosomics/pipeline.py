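"""End-to-end orchestration: detect -> annotate -> classify -> tree."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .arch import ArchitectureError, ScaffoldinArchitecture
from .classify import assign_nomenclature
from .detect import DetectionConfig, ModuleHit, ReferenceProfile, annotate_protein, scan_profile, detect_signal_peptide, resolve_overlaps
from .phylo import nj_tree, pairwise_distances, to_newick
from . import fileio

log = logging.getLogger("cellulosomics")


def detect_proteome(records: list[tuple[str, str]],
                    profiles: dict[str, ReferenceProfile],
                    config: DetectionConfig) -> list[ModuleHit]:
    """Scan every protein with every profile; cross-class overlap-resolved."""
    all_hits: list[ModuleHit] = []
    for pid, seq in records:
        hits: list[ModuleHit] = []
        for profile in profiles.values():
            hits.extend(scan_profile(seq, profile, config, protein_id=pid))
        accepted = resolve_overlaps(hits, config.overlap_fraction)
        accepted.sort(key=lambda h: h.start)
        all_hits.extend(accepted)
    return all_hits


def architectures_from_hits(records: list[tuple[str, str]],
                            hits: list[ModuleHit]) -> list[ScaffoldinArchitecture]:
    """Token architectures from resolved hits plus the signal heuristic."""
    from .arch import parse_architecture
    by_protein: dict[str, list[ModuleHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for pid, seq in records:
        phits = sorted(by_protein.get(pid, []), key=lambda h: h.start)
        tokens = [h.module_class for h in phits]
        if detect_signal_peptide(seq).present:
            tokens = ["SIGN"] + tokens
        if not tokens:
            continue
        out.append(parse_architecture(" ".join(tokens), protein_id=pid, name=pid))
    return out


def run_pipeline(proteome_fasta: str | Path,
                 profiles: dict[str, ReferenceProfile],
                 config: DetectionConfig,
                 outdir: str | Path) -> dict:
    """Full workflow on a proteome FASTA; writes stage outputs and a report.

    Outputs: ``hits.tsv``, ``architectures.json``, ``classifications.tsv``,
    ``cohesins.nwk`` (when >= 3 cohesin hits).  Raises on an empty FASTA or
    missing reference profiles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = fileio.read_fasta(proteome_fasta)
    if not records:
        raise ValueError("no sequences in input FASTA")
    if not any(p in profiles for p in ("Coh1", "Coh2")):
        raise ValueError("missing reference profiles for module class Coh1/Coh2")
    if not any(p in profiles for p in ("Doc1", "XDoc2")):
        raise ValueError("missing reference profiles for module class Doc1/XDoc2")

    hits = detect_proteome(records, profiles, config)
    fileio.write_hits_tsv(hits, outdir / "hits.tsv")
    log.info("detection: %d hits on %d proteins", len(hits),
             len({h.protein_id for h in hits}))

    archs = architectures_from_hits(records, hits)
    (outdir / "architectures.json").write_text(
        json.dumps([a.to_dict() for a in archs], indent=2) + "\n")
    log.info("annotation: %d architectures", len(archs))

    rows = []
    for a in archs:
        try:
            call = assign_nomenclature(a)
            rows.append({"name": a.name, "label": call.label,
                         "rationale": call.rationale})
        except (ValueError, ArchitectureError):
            rows.append({"name": a.name, "label": "not_cellulosomal",
                         "rationale": "no_cohesin_or_dockerin"})
    pd.DataFrame(rows, columns=["name", "label", "rationale"]).to_csv(
        outdir / "classifications.tsv", sep="\t", index=False)

    seq_by_id = dict(records)
    cohesins = [(f"{h.protein_id}|{h.start}",
                 seq_by_id[h.protein_id][h.start:h.end])
                for h in hits if h.module_class in ("Coh1", "Coh2")]
    if len(cohesins) >= 3:
        tree = nj_tree(pairwise_distances(cohesins))
        (outdir / "cohesins.nwk").write_text(to_newick(tree))
    report = {
        "n_proteins": len(records),
        "n_hits": len(hits),
        "n_architectures": len(archs),
        "n_cohesin_hits": len(cohesins),
        "hit_counts_by_class": dict(pd.Series(
            [h.module_class for h in hits]).value_counts().sort_index())
        if hits else {},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=int) + "\n")
    return report
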