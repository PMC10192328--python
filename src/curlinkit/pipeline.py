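"""End-to-end orchestration: mine -> classify -> logo, and structure
reports, with a run manifest tying every output to its configuration."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, io, mining, motifs
from .geometry import geometry_report, read_structure

DEFAULT_CONFIG = {
    "hbond_cutoff": 3.5,
    "clash_cutoff": 2.0,
    "sasa_probe_radius": 1.4,
    "sasa_point_number": 500,
    "cs_fraction_threshold": motifs.CS_FRACTION_THRESHOLD,
    "d_fraction_threshold": motifs.D_FRACTION_THRESHOLD,
    "degenerate_length": 28,
}


class EmptyInputError(ValueError):
    pass


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    inputs: dict = field(default_factory=dict)      # path -> sha256
    version: str = __version__
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timestamp: float = 0.0

    def write(self, path) -> None:
        payload = {
            "version": self.version,
            "inputs": self.inputs,
            "config": self.config,
            "config_hash": hashlib.sha256(
                json.dumps(self.config, sort_keys=True).encode()).hexdigest(),
            "counts": self.counts,
            "timestamp": self.timestamp,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def run_sequence_pipeline(fasta_path, out_prefix, config: dict | None = None):
    """FASTA -> repeat annotation TSV/JSON + subunit classes + PFM + manifest."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    records = io.read_fasta(fasta_path)
    if not records:
        raise EmptyInputError(f"no sequences in {fasta_path}")
    dataset = mining.annotate_dataset(records)
    motifs.classify_dataset(dataset)
    windows = mining.extract_kernel_windows(dataset)

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    io.write_annotation_tsv(dataset, f"{prefix}.repeats.tsv")
    io.write_subunit_tsv(dataset, f"{prefix}.subunits.tsv")
    io.write_annotation_json(dataset, f"{prefix}.annotations.json")
    pfm = None
    if windows:
        pfm = motifs.build_pfm(windows)
        io.write_pfm(pfm, f"{prefix}.pfm")

    manifest = RunManifest(
        inputs={str(fasta_path): _sha256(fasta_path)},
        config=cfg,
        counts={
            "sequences": len(dataset),
            "repeats": sum(len(a.repeats) for a in dataset),
            "kernel_windows": len(windows),
        },
        timestamp=time.time(),
    )
    manifest.write(f"{prefix}.manifest.json")
    return dataset, pfm, manifest


def run_structure_pipeline(structure_path, annotation_path, out_prefix,
                           config: dict | None = None):
    """Structure + annotation -> geometry report JSON + manifest."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    annotations = io.read_annotation_json(annotation_path)
    if not annotations:
        raise EmptyInputError(f"no annotations in {annotation_path}")
    model = read_structure(structure_path, annotation=annotations[0])
    report = geometry_report(
        model,
        hbond_cutoff=cfg["hbond_cutoff"],
        probe_radius=cfg["sasa_probe_radius"],
        point_number=cfg["sasa_point_number"],
    )
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.geometry.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1)
        fh.write("\n")
    with open(f"{prefix}.geometry.tsv", "w", encoding="utf-8") as fh:
        d = report.to_dict()
        keys = [k for k in d if k != "conventions"]
        fh.write("\t".join(keys) + "\n")
        fh.write("\t".join(str(d[k]) for k in keys) + "\n")
    manifest = RunManifest(
        inputs={str(structure_path): _sha256(structure_path),
                str(annotation_path): _sha256(annotation_path)},
        config=cfg,
        counts={"residues": model.n_residues,
                "repeats": len(model.repeat_ids)},
        timestamp=time.time(),
    )
    manifest.write(f"{prefix}.manifest.json")
    return report, manifest
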