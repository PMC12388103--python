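"""CSV readers/writers, unit handling, inner-filter correction, config.

CSV is the sole exchange format. Files carry metadata as leading
``# key: value`` comment lines and a plain header row; concentration columns
declare their unit in the column name (``quencher_conc_uM``) and are
converted to mol/L on read. Numeric round trips are exact to better than
1e-12 relative (17 significant digits on write); parsing is
locale-independent (dot decimal separator).
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    DEFAULT_TAU0_S,
    DEFAULT_TEMPERATURE_K,
    EEM,
    AbsorptionSpectrum,
    EmissionSpectrum,
    JobSeries,
    TitrationSeries,
    ValidationError,
    require_valid,
)

__all__ = [
    "CONCENTRATION_UNITS",
    "read_titration_csv",
    "write_titration_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_eem_csv",
    "write_eem_csv",
    "read_job_csv",
    "write_job_csv",
    "correct_inner_filter",
    "load_config",
]

logger = logging.getLogger("hsabind")

#: Multiplier from declared unit to mol/L.
CONCENTRATION_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}

_FMT = "%.17g"  # round-trip exact for float64


def _fmt(x: float) -> str:
    return _FMT % x


def _read_metadata_and_table(path) -> tuple[dict[str, str], pd.DataFrame]:
    text = Path(path).read_text()
    meta: dict[str, str] = {}
    body_lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            body_lines.append((lineno, line))
    if not body_lines:
        raise ValidationError(f"{path}: no table found")
    buf = _io.StringIO("\n".join(line for _, line in body_lines))
    try:
        df = pd.read_csv(buf)
    except ValueError as exc:
        raise ValidationError(f"{path}: cannot parse CSV table: {exc}") from exc
    # locate non-numeric cells with their original row numbers
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size:
            file_row = body_lines[1 + bad[0]][0]  # +1 skips the header line
            raise ValidationError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r} at line {file_row}"
            )
        df[col] = coerced
    return meta, df


def _conc_column(df: pd.DataFrame, stem: str, units_declaration: str | None):
    """Find ``<stem>_<unit>`` (or bare ``<stem>``) and return values in mol/L."""
    for col in df.columns:
        if col == stem or col.startswith(stem + "_"):
            suffix = col[len(stem) + 1 :] if col != stem else ""
            unit = units_declaration or suffix or "M"
            if unit not in CONCENTRATION_UNITS:
                raise ValidationError(f"unknown concentration unit {unit!r}")
            return df[col].to_numpy(dtype=float) * CONCENTRATION_UNITS[unit]
    raise ValidationError(f"no column matching {stem!r} in {list(df.columns)}")


def read_titration_csv(path, units_declaration: str | None = None) -> TitrationSeries:
    """Read a fluorescence titration table.

    Expected columns: ``quencher_conc_<unit>`` and ``intensity``; metadata
    lines may set ``protein_conc_M``, ``temperature_K``, ``tau0_s``,
    ``analysis_wavelength_nm`` and ``label``. Rows are sorted by
    concentration; a missing zero-concentration row is a validation error;
    a missing tau0 defaults to 6.3e-9 s with a logged warning.
    """
    meta, df = _read_metadata_and_table(path)
    q = _conc_column(df, "quencher_conc", units_declaration)
    if "intensity" not in df.columns:
        raise ValidationError(f"{path}: missing 'intensity' column")
    f = df["intensity"].to_numpy(dtype=float)
    order = np.argsort(q)
    q, f = q[order], f[order]
    if "tau0_s" in meta:
        tau0 = float(meta["tau0_s"])
    else:
        tau0 = DEFAULT_TAU0_S
        logger.warning(
            "%s: no tau0_s metadata; defaulting to %.2g s", path, DEFAULT_TAU0_S
        )
    wl = meta.get("analysis_wavelength_nm", "lambda_max")
    series = TitrationSeries(
        protein_conc=float(meta.get("protein_conc_M", 2.0e-6)),
        quencher_concs=q,
        intensities=f,
        temperature=float(meta.get("temperature_K", DEFAULT_TEMPERATURE_K)),
        tau0=tau0,
        analysis_wavelength=float(wl) if wl not in ("lambda_max", "integrated") else wl,
        label=meta.get("label", ""),
    )
    require_valid(series)
    return series


def write_titration_csv(series: TitrationSeries, path, units: str = "uM") -> None:
    scale = CONCENTRATION_UNITS[units]
    with open(path, "w") as fh:
        fh.write(f"# protein_conc_M: {_fmt(series.protein_conc)}\n")
        fh.write(f"# temperature_K: {_fmt(series.temperature)}\n")
        fh.write(f"# tau0_s: {_fmt(series.tau0)}\n")
        fh.write(f"# analysis_wavelength_nm: {series.analysis_wavelength}\n")
        if series.label:
            fh.write(f"# label: {series.label}\n")
        fh.write(f"quencher_conc_{units},intensity\n")
        for q, f in zip(series.quencher_concs, series.intensities):
            fh.write(f"{_fmt(q / scale)},{_fmt(f)}\n")


def read_spectrum_csv(path, kind: str = "emission"):
    """Read an emission (``wavelength_nm,intensity``) or absorption
    (``wavelength_nm,absorbance``) spectrum."""
    meta, df = _read_metadata_and_table(path)
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if kind == "emission":
        obj = EmissionSpectrum(
            excitation_wavelength=float(meta.get("excitation_nm", 295.0)),
            wavelengths=wl,
            intensities=df["intensity"].to_numpy(dtype=float),
            label=meta.get("label", ""),
        )
    elif kind == "absorption":
        obj = AbsorptionSpectrum(
            wavelengths=wl,
            absorbance=df["absorbance"].to_numpy(dtype=float),
            label=meta.get("label", ""),
        )
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")
    require_valid(obj)
    return obj


def write_spectrum_csv(spectrum, path) -> None:
    with open(path, "w") as fh:
        if isinstance(spectrum, EmissionSpectrum):
            fh.write(f"# excitation_nm: {_fmt(spectrum.excitation_wavelength)}\n")
            if spectrum.label:
                fh.write(f"# label: {spectrum.label}\n")
            fh.write("wavelength_nm,intensity\n")
            values = spectrum.intensities
        else:
            if spectrum.label:
                fh.write(f"# label: {spectrum.label}\n")
            fh.write("wavelength_nm,absorbance\n")
            values = spectrum.absorbance
        for w, v in zip(spectrum.wavelengths, values):
            fh.write(f"{_fmt(w)},{_fmt(v)}\n")


def read_eem_csv(path, form: str = "long") -> EEM:
    """Read an excitation-emission matrix.

    long form: columns ``excitation_nm, emission_nm, intensity`` covering the
    full grid product; wide form: rows = excitation, columns = emission, the
    top-left header cell named ``ex_nm``.
    """
    meta, df = _read_metadata_and_table(path)
    if form == "long":
        ex = np.unique(df["excitation_nm"].to_numpy(dtype=float))
        em = np.unique(df["emission_nm"].to_numpy(dtype=float))
        z = np.full((ex.size, em.size), np.nan)
        ei = np.searchsorted(ex, df["excitation_nm"].to_numpy(dtype=float))
        mi = np.searchsorted(em, df["emission_nm"].to_numpy(dtype=float))
        z[ei, mi] = df["intensity"].to_numpy(dtype=float)
        if np.isnan(z).any():
            raise ValidationError(f"{path}: long-form EEM does not cover the grid")
    elif form == "wide":
        ex = df["ex_nm"].to_numpy(dtype=float)
        em = np.array([float(c) for c in df.columns if c != "ex_nm"])
        z = df[[c for c in df.columns if c != "ex_nm"]].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown EEM form {form!r}")
    eem = EEM(
        excitation_wavelengths=ex,
        emission_wavelengths=em,
        intensities=z,
        label=meta.get("label", ""),
    )
    require_valid(eem)
    return eem


def write_eem_csv(eem: EEM, path, form: str = "long") -> None:
    with open(path, "w") as fh:
        if eem.label:
            fh.write(f"# label: {eem.label}\n")
        if form == "long":
            fh.write("excitation_nm,emission_nm,intensity\n")
            for i, ex in enumerate(eem.excitation_wavelengths):
                for j, em in enumerate(eem.emission_wavelengths):
                    fh.write(f"{_fmt(ex)},{_fmt(em)},{_fmt(eem.intensities[i, j])}\n")
        elif form == "wide":
            fh.write("ex_nm," + ",".join(_fmt(m) for m in eem.emission_wavelengths))
            fh.write("\n")
            for i, ex in enumerate(eem.excitation_wavelengths):
                fh.write(
                    _fmt(ex)
                    + ","
                    + ",".join(_fmt(v) for v in eem.intensities[i])
                    + "\n"
                )
        else:
            raise ValueError(f"unknown EEM form {form!r}")


def read_job_csv(path) -> JobSeries:
    """Read a continuous-variation series: columns ``mole_fraction_protein,
    signal``; metadata ``total_conc_M``."""
    meta, df = _read_metadata_and_table(path)
    series = JobSeries(
        total_conc=float(meta.get("total_conc_M", 2.0e-6)),
        mole_fractions=df["mole_fraction_protein"].to_numpy(dtype=float),
        signal=df["signal"].to_numpy(dtype=float),
        label=meta.get("label", ""),
    )
    require_valid(series)
    return series


def write_job_csv(series: JobSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# total_conc_M: {_fmt(series.total_conc)}\n")
        if series.label:
            fh.write(f"# label: {series.label}\n")
        fh.write("mole_fraction_protein,signal\n")
        for chi, s in zip(series.mole_fractions, series.signal):
            fh.write(f"{_fmt(chi)},{_fmt(s)}\n")


def correct_inner_filter(intensity: float, a_ex: float, a_em: float) -> float:
    """Inner-filter-effect correction F_corr = F_obs·10^((A_ex + A_em)/2).

    A_ex / A_em are the sample absorbances at the excitation and emission
    wavelengths. Disabled by default throughout the pipeline; apply before
    fitting when absorbances were recorded.
    """
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be non-negative")
    return intensity * 10.0 ** ((a_ex + a_em) / 2.0)


def load_config(path) -> dict:
    """Load a YAML run configuration; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
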