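"""File-format plumbing: FASTA, CSV tables, YAML config, checksums."""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from studlines.pedigree import Pedigree


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_mares_csv(path) -> pd.DataFrame:
    """Mare table: sample_id,family[,haplotype][,year]."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mare CSV missing columns: {sorted(missing)}")
    return df


def read_pedigree_csv(path, *, strict: bool = True) -> Pedigree:
    """Pedigree CSV: id,sire,dam,sex,birth_year,family; empty = unknown."""
    df = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str, "sex": str, "family": str})
    return Pedigree.from_frame(df, strict=strict)


def read_msy_csv(path) -> pd.DataFrame:
    """Pre-called MSY genotype CSV: sample_id,YE3,YE17,YXX."""
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "YE3", "YE17", "YXX"} - set(df.columns)
    if missing:
        raise ValueError(f"MSY CSV missing columns: {sorted(missing)}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
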