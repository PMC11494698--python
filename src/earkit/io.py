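"""Readers and writers for the pipeline's file formats.

Motif libraries travel as FASTA (id in the header, library membership and
optional ground truth / predicted class as key=value pairs in the
description); plate, Cq, summary and n-gram tables as tidy CSV; evaluation
results and run configs as JSON / flat YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import Motif, ParameterError


def write_motifs_fasta(motifs: Iterable[Motif], path: str | Path) -> None:
    """Write motifs as FASTA with key=value metadata in the description."""
    records = []
    for m in motifs:
        fields = [f"library={m.library}"]
        if m.true_strength is not None:
            fields.append(f"true_strength={m.true_strength:.6g}")
        if m.predicted_class is not None:
            fields.append(f"predicted_class={m.predicted_class}")
        records.append(
            SeqRecord(Seq(m.sequence), id=m.id, description=" ".join(fields))
        )
    SeqIO.write(records, str(path), "fasta")


def read_motifs_fasta(path: str | Path) -> list[Motif]:
    """Read a motif FASTA written by :func:`write_motifs_fasta`."""
    motifs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta: dict[str, str] = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        motifs.append(
            Motif(
                id=rec.id,
                sequence=str(rec.seq),
                library=meta.get("library", "naturalEAR"),
                true_strength=(float(meta["true_strength"])
                               if "true_strength" in meta else None),
                predicted_class=meta.get("predicted_class"),
            )
        )
    if not motifs:
        raise ParameterError(f"no sequences found in {path}")
    return motifs


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"construct_id", "plant_id", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"plate CSV lacks columns {sorted(missing)}")
    return df


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"Cq CSV lacks columns {sorted(missing)}")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_class_lists(classes: dict[str, Sequence[str]], out_dir: str | Path
                      ) -> None:
    """One plain-text gram list per class (strong.txt, moderate.txt, ...)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cls, grams in classes.items():
        (out / f"{cls}.txt").write_text("\n".join(grams) + "\n")


def read_class_lists(in_dir: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for cls in ("weak", "moderate", "strong"):
        p = Path(in_dir) / f"{cls}.txt"
        out[cls] = (
            [l for l in p.read_text().splitlines() if l.strip()]
            if p.exists() else []
        )
    return out


def write_config(config: dict, path: str | Path) -> None:
    """Flat key-value run config (YAML)."""
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(loaded, dict):
        raise ParameterError("config must be a flat key-value mapping")
    return loaded
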