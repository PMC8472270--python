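"""CSV readers and writers for the tabular interchange formats.

ACF curves: ``lag_s,g2_minus_1``. Intensity series:
``conc_mg_ml,I_sample,I_solvent,I_toluene``. Association series:
``conc_mM,m_rel[,m_rel_err],r_s_nm[,r_s_err]`` (error columns hold a
single relative error). Spectra: ``wavelength_nm,signal``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import AssociationSeries
from .scattering import AcfCurve, IntensityRecord
from .spectro import Spectrum

__all__ = [
    "read_acf_csv", "write_acf_csv",
    "read_intensity_csv", "write_intensity_csv",
    "read_association_csv", "write_association_csv",
    "read_spectrum_csv", "write_spectrum_csv",
]


def read_acf_csv(path) -> AcfCurve:
    df = pd.read_csv(path)
    return AcfCurve(
        lags_s=df["lag_s"].to_numpy(), g2_minus_1=df["g2_minus_1"].to_numpy()
    )


def write_acf_csv(acf: AcfCurve, path) -> None:
    pd.DataFrame({"lag_s": acf.lags_s, "g2_minus_1": acf.g2_minus_1}).to_csv(
        path, index=False
    )


def read_intensity_csv(path) -> list[IntensityRecord]:
    df = pd.read_csv(path)
    return [
        IntensityRecord(
            mean_intensity_sample=row.I_sample,
            mean_intensity_solvent=row.I_solvent,
            mean_intensity_reference=row.I_toluene,
            concentration_mg_ml=row.conc_mg_ml,
        )
        for row in df.itertuples()
    ]


def write_intensity_csv(records, path) -> None:
    pd.DataFrame(
        {
            "conc_mg_ml": [r.concentration_mg_ml for r in records],
            "I_sample": [r.mean_intensity_sample for r in records],
            "I_solvent": [r.mean_intensity_solvent for r in records],
            "I_toluene": [r.mean_intensity_reference for r in records],
        }
    ).to_csv(path, index=False)


def read_association_csv(path) -> AssociationSeries:
    df = pd.read_csv(path)
    kwargs = {}
    if "m_rel_err" in df:
        kwargs["m_rel_relerr"] = float(df["m_rel_err"].iloc[0])
    if "r_s_nm" in df:
        kwargs["r_s_nm"] = df["r_s_nm"].to_numpy()
        if "r_s_err" in df:
            kwargs["r_s_relerr"] = float(df["r_s_err"].iloc[0])
    return AssociationSeries(
        concentrations_mM=df["conc_mM"].to_numpy(),
        m_rel=df["m_rel"].to_numpy(),
        **kwargs,
    )


def write_association_csv(series: AssociationSeries, path) -> None:
    data = {
        "conc_mM": series.concentrations_mM,
        "m_rel": series.m_rel,
        "m_rel_err": np.full(series.m_rel.shape, series.m_rel_relerr),
    }
    if series.r_s_nm is not None:
        data["r_s_nm"] = series.r_s_nm
        data["r_s_err"] = np.full(series.r_s_nm.shape, series.r_s_relerr)
    pd.DataFrame(data).to_csv(path, index=False)


def read_spectrum_csv(path, **metadata) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        signal=df["signal"].to_numpy(),
        **metadata,
    )


def write_spectrum_csv(spec: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spec.wavelengths_nm, "signal": spec.signal}
    ).to_csv(path, index=False)
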