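"""Readers/writers for the artifact formats: FASTA sequences, property
tables (CSV), PMF/EOS curves (CSV), run configuration (YAML) and logging."""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .forcefield import AMINO_ACIDS
from .property_engines import EOSCurve, PMFCurve, PropertyRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_property_csv",
    "read_property_csv",
    "write_pmf_csv",
    "read_eos_csv",
    "load_config",
    "dump_config",
    "config_hash",
]

PROPERTY_COLUMNS = ["id", "B2", "B2_se", "phase_sep", "rho_c", "rho_c_se",
                    "D", "D_se", "provenance"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs; mixed case is uppercased with a warning,
    non-amino-acid characters are rejected naming the record."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"record {rec.id}: lowercase residues uppercased")
            seq = seq.upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"record {rec.id}: non-amino-acid character(s) {sorted(bad)}")
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs at 60 columns."""
    seq_records = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def write_property_csv(records: dict[str, PropertyRecord] | list[PropertyRecord],
                       path: str | Path, ids: list[str] | None = None) -> None:
    if isinstance(records, dict):
        items = list(records.items())
    else:
        items = [(ids[i] if ids else f"seq{i}", r) for i, r in enumerate(records)]
    rows = []
    for rid, r in items:
        rows.append({
            "id": rid, "B2": r.B2, "B2_se": r.B2_se,
            "phase_sep": int(r.phase_separates),
            "rho_c": r.rho_c, "rho_c_se": r.rho_c_se,
            "D": r.D, "D_se": r.D_se, "provenance": r.provenance,
        })
    pd.DataFrame(rows, columns=PROPERTY_COLUMNS).to_csv(path, index=False)


def read_property_csv(path: str | Path) -> dict[str, PropertyRecord]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        phase = bool(row["phase_sep"])
        out[str(row["id"])] = PropertyRecord(
            sequence=str(row["id"]), B2=float(row["B2"]),
            B2_se=float(row.get("B2_se", 0.0) or 0.0),
            phase_separates=phase,
            rho_c=float(row["rho_c"]) if phase and pd.notna(row["rho_c"]) else None,
            rho_c_se=float(row["rho_c_se"]) if phase and pd.notna(row["rho_c_se"]) else None,
            D=float(row["D"]) if phase else None,
            D_se=float(row["D_se"]) if phase and pd.notna(row["D_se"]) else None,
            provenance=str(row.get("provenance", "external")),
        )
    return out


def write_pmf_csv(pmf: PMFCurve, path: str | Path) -> None:
    se = pmf.u_se if pmf.u_se is not None else np.zeros_like(pmf.r)
    pd.DataFrame({"r": pmf.r, "u": pmf.u, "u_se": se}).to_csv(path, index=False)


def read_eos_csv(path: str | Path, temperature: float = 300.0) -> EOSCurve:
    df = pd.read_csv(path)
    se = df["pressure_se"].to_numpy() if "pressure_se" in df else None
    return EOSCurve(densities=df["density"].to_numpy(),
                    pressures=df["pressure"].to_numpy(),
                    pressure_se=se, temperature=temperature)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, stamped on outputs."""
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
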