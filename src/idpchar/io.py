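"""Readers and writers for the plain-text formats the package consumes.

FASTA via Biopython; 3-column whitespace-delimited SAXS ``.dat``
(s, I, sigma; ``#`` comments, sigma optional); CD tables and SEC
calibration standards as CSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cdspec import CDSpectrum
from .saxs import SAXSCurve
from .seqdis import SequenceRecord


def read_fasta(path: str | Path, record_id: str | None = None) -> SequenceRecord:
    """First record of a FASTA file (or the one matching ``record_id``)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is not None:
        for rec in records:
            if rec.id == record_id:
                return SequenceRecord(id=rec.id, residues=str(rec.seq))
        raise KeyError(f"record {record_id!r} not found in {path}")
    rec = records[0]
    return SequenceRecord(id=rec.id, residues=str(rec.seq))


def read_dat(path: str | Path, units: str = "A") -> SAXSCurve:
    """SAXS curve from a 2- or 3-column whitespace text file.

    Columns are s, I and (optionally) sigma; ``#`` starts a comment.
    ``units`` declares the s units ('A' for A^-1, 'nm' for nm^-1) -- they
    are never guessed from magnitudes.
    """
    data = np.loadtxt(str(path), comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (s, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(s=data[:, 0], intensity=data[:, 1], sigma=sigma,
                     units=units, label=str(path))


def write_dat(path: str | Path, curve: SAXSCurve, header: str = "") -> None:
    cols = [curve.s, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(str(path), np.column_stack(cols),
               header=header or "s[A^-1] I sigma", fmt="%.8e")


def read_cd_csv(path: str | Path, units: str = "mdeg") -> CDSpectrum:
    """CD spectrum from CSV with columns wavelength_nm, signal[, ht_v]."""
    df = pd.read_csv(path)
    required = {"wavelength_nm", "signal"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: CD CSV needs columns {sorted(required)}")
    ht = df["ht_v"].to_numpy(float) if "ht_v" in df.columns else None
    return CDSpectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        units=units,
        ht_volts=ht,
        label=str(path),
    )


def write_cd_csv(path: str | Path, spectrum: CDSpectrum) -> None:
    data = {"wavelength_nm": spectrum.wavelength_nm, "signal": spectrum.signal}
    if spectrum.ht_volts is not None:
        data["ht_v"] = spectrum.ht_volts
    pd.DataFrame(data).to_csv(path, index=False)


def read_sec_standards(path: str | Path) -> list[tuple[str, float, float, float]]:
    """SEC standards from CSV: name, mm_da, rs_angstrom, ve_ml."""
    df = pd.read_csv(path)
    required = {"name", "mm_da", "rs_angstrom", "ve_ml"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: SEC CSV needs columns {sorted(required)}")
    return [
        (str(row["name"]), float(row["mm_da"]), float(row["rs_angstrom"]),
         float(row["ve_ml"]))
        for _, row in df.iterrows()
    ]


def write_sec_standards(path: str | Path, standards) -> None:
    pd.DataFrame(
        standards, columns=["name", "mm_da", "rs_angstrom", "ve_ml"]
    ).to_csv(path, index=False)
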