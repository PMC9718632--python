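"""Packaged reference data for the Yinqiao powder quality study.

These small CSVs transcribe the published validation tables of the
dual-wavelength HPLC quality evaluation of Yinqiao powder (a ten-herb
formula), and are the inputs the acceptance checks recompute from:

* ``calibration_lines.csv`` — external-standard regression lines
  (area vs µg injected) of the seven reference substances at 237/327 nm,
  with correlation coefficient and linear range.
* ``rcf_replicates.csv`` — six replicate relative correction factors per
  analyte (forsythoside A internal standard; phillyrin/arctiin at 237 nm,
  the four caffeoylquinic acids at 327 nm).
* ``rcf_means.csv`` — the published replicate means and RSDs.
* ``content_pairs.csv`` — per-batch contents (mg/g) by the external
  standard method (ESM) and by single-marker quantitation (QAMS) with the
  published relative errors; forsythoside A rows carry ESM only (it is
  the internal standard).
* ``standard_concentrations.csv`` — mixed reference-solution
  concentrations (µg/mL) used for correction-factor measurement.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_calibration_lines",
    "load_rcf_replicates",
    "load_rcf_means",
    "load_content_pairs",
    "load_standard_concentrations",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("chromqc.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_calibration_lines() -> pd.DataFrame:
    """Published calibration lines: wavelength, analyte, slope, intercept, r, linear range (µg)."""
    return _read("calibration_lines.csv")


def load_rcf_replicates() -> pd.DataFrame:
    """Six replicate relative correction factors per analyte and wavelength."""
    return _read("rcf_replicates.csv")


def load_rcf_means() -> pd.DataFrame:
    """Published mean relative correction factors and their RSDs."""
    return _read("rcf_means.csv")


def load_content_pairs(pairs_only: bool = False) -> pd.DataFrame:
    """Per-batch ESM and QAMS contents (mg/g) with published relative errors.

    With ``pairs_only`` the internal-standard rows (ESM content only,
    no QAMS value) are dropped, leaving the 60 method-comparison pairs.
    """
    df = _read("content_pairs.csv")
    if pairs_only:
        df = df.dropna(subset=["qams_mg_g"]).reset_index(drop=True)
    return df


def load_standard_concentrations() -> dict[str, float]:
    """Mixed reference-solution concentrations, µg/mL, keyed by analyte."""
    df = _read("standard_concentrations.csv")
    return dict(zip(df["analyte"], df["concentration_ug_per_mL"].astype(float)))
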