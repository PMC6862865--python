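"""Extracellular-flux bioenergetics.

Turns per-well OCR/ECAR traces from a mito-stress-test run (sequential
oligomycin, FCCP, rotenone/antimycin A injections) into respiration
summaries, spare respiratory capacity (SRC), the glycolytic proton
production rate (PPR_glyc), and oxidative vs glycolytic ATP production
rates.

The rate partitioning follows the standard stoichiometric framework for
splitting total ATP production between oxidative phosphorylation and
glycolysis::

    OCR_mito  = OCR_tot - OCR_R/A
    PPR_glyc  = ECAR_tot / BP - OCR_mito * maxH/O2 * 10^(pH-pK1) / (1 + 10^(pH-pK1))
    ATP_ox    = OCR_coupled * 2 * P/O_oxphos + OCR_mito * 2 * P/O_TCA
    ATP_glyc  = PPR_glyc * ATP/lactate + OCR_mito * 2 * P/O_glyc
    ATP_total = ATP_ox + ATP_glyc

where a P/O ratio is mol ATP produced per mol oxygen *atom* consumed
(hence the factors of 2 on rates expressed per mol O2) and the second
term of PPR_glyc removes acidification caused by CO2 hydration in the
TCA cycle rather than by lactate export.

All stoichiometric constants are configuration (`BioenergeticConstants`),
never hard-coded: assay media differ in buffering power and substrate mix,
and every result table records the constants used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError, SummaryError

#: Injection phases in assay order.
PHASES = ("basal", "oligo", "fccp", "rot_aa")

PLATE_COLUMNS = ("well", "cycle", "phase", "time_min", "OCR", "ECAR")


@dataclass
class FluxPlate:
    """Per-well OCR/ECAR time series with optional normalization signal.

    Parameters
    ----------
    data:
        Long table with columns ``well, cycle, phase, time_min, OCR, ECAR``;
        ``phase`` is one of :data:`PHASES`, OCR in pmol O2/min, ECAR in
        mpH/min.
    normalization:
        Optional per-well signal (e.g. nuclei-stain intensity, a.u.) used
        to correct for cell number.
    """

    data: pd.DataFrame
    normalization: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"flux plate missing columns: {missing}")
        vals = self.data[["OCR", "ECAR"]].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("OCR/ECAR values must be finite")
        order = {p: i for i, p in enumerate(PHASES)}
        bad = set(self.data["phase"]) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        for well, g in self.data.groupby("well", sort=False):
            cyc = g["cycle"].to_numpy()
            if np.any(np.diff(cyc) <= 0):
                raise ValueError(f"cycle indices not strictly increasing in well {well}")
            ranks = g["phase"].map(order).to_numpy()
            if np.any(np.diff(ranks) < 0):
                raise ValueError(f"phases out of order in well {well}")

    @property
    def wells(self) -> list:
        return list(dict.fromkeys(self.data["well"]))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)
        if self.normalization is not None:
            norm_path = str(path).rsplit(".", 1)[0] + "_norm.csv"
            self.normalization.rename("signal").rename_axis("well").reset_index().to_csv(
                norm_path, index=False
            )


def read_flux_csv(path, column_map: Mapping[str, str] | None = None,
                  normalization: pd.Series | None = None) -> FluxPlate:
    """Read a flux plate CSV, optionally renaming a Wave-like export dialect.

    ``column_map`` maps source column names to the canonical names in
    :data:`PLATE_COLUMNS` (e.g. ``{"measurement": "cycle", "time": "time_min"}``).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    df = df[[c for c in df.columns if c in PLATE_COLUMNS or c == "group"]]
    return FluxPlate(df, normalization=normalization)


@dataclass(frozen=True)
class BioenergeticConstants:
    """Medium and stoichiometry parameters for ATP-rate partitioning.

    Defaults correspond to a HEPES-buffered glucose/pyruvate medium at
    pH 7.4 and the conventional glucose-oxidation stoichiometries; all
    are assay-specific and should be overridden when known.

    Attributes
    ----------
    ph : assay medium pH (unitless).
    pk1 : first dissociation constant of carbonic acid (unitless).
    buffering_power : mpH change per pmol H+ in the measurement volume.
    max_h_per_o2 : maximal H+ released per O2 consumed by CO2 hydration.
    po_oxphos : ATP per O atom from oxidative phosphorylation.
    po_tca : ATP per O atom from TCA-cycle substrate-level phosphorylation.
    po_glyc : ATP per O atom attributable to glycolysis-linked oxidation.
    atp_per_lactate : ATP per lactate exported (unitless).
    """

    ph: float = 7.4
    pk1: float = 6.093
    buffering_power: float = 0.1
    max_h_per_o2: float = 1.0
    po_oxphos: float = 2.486
    po_tca: float = 0.121
    po_glyc: float = 0.167
    atp_per_lactate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("buffering_power", "max_h_per_o2", "po_oxphos",
                     "po_tca", "po_glyc", "atp_per_lactate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("ph", "pk1"):
            v = getattr(self, name)
            if not 0 < v < 14:
                raise ValueError(f"{name} must lie in (0, 14)")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize_phases(plate: FluxPlate, mode: str = "mean") -> pd.DataFrame:
    """Per-well respiration summary from phase-level OCR means.

    Each phase value is the mean OCR over that phase's measurement cycles
    (``mode="last"`` instead uses only the final cycle of each
    post-injection phase, a common choice for post-oligomycin plateaus;
    basal always averages all basal cycles). Derived quantities:

    - ``ocr_mito``    = basal - rot/AA (mitochondrial respiration)
    - ``ocr_coupled`` = basal - post-oligomycin (ATP-synthase-linked)
    - ``ocr_leak``    = post-oligomycin - rot/AA (proton leak)
    - ``src_pct``     = maximal / basal * 100 (spare respiratory capacity)

    ``ecar_tot`` is the basal-phase mean ECAR, the value fed to
    :func:`compute_ppr_glyc`.

    Raises
    ------
    SummaryError
        If any well is missing a phase (names the well and phase).
    """
    if mode not in ("mean", "last"):
        raise ValueError("mode must be 'mean' or 'last'")
    rows = []
    for well, g in plate.data.groupby("well", sort=False):
        phase_ocr = {}
        for phase in PHASES:
            sub = g[g["phase"] == phase]
            if sub.empty:
                raise SummaryError(f"well {well!r} has no cycles in phase {phase!r}")
            if mode == "last" and phase != "basal":
                phase_ocr[phase] = float(sub["OCR"].iloc[-1])
            else:
                phase_ocr[phase] = float(sub["OCR"].mean())
        ecar_tot = float(g.loc[g["phase"] == "basal", "ECAR"].mean())
        basal = phase_ocr["basal"]
        post_oligo = phase_ocr["oligo"]
        maximal = phase_ocr["fccp"]
        rot_aa = phase_ocr["rot_aa"]
        rows.append({
            "well": well,
            "ocr_basal": basal,
            "ocr_post_oligo": post_oligo,
            "ocr_max": maximal,
            "ocr_rot_aa": rot_aa,
            "ocr_mito": basal - rot_aa,
            "ocr_coupled": basal - post_oligo,
            "ocr_leak": post_oligo - rot_aa,
            "src_pct": maximal / basal * 100.0 if basal != 0 else np.nan,
            "ecar_tot": ecar_tot,
        })
    return pd.DataFrame(rows).set_index("well")


def compute_ppr_glyc(ocr_mito, ecar_tot, k: BioenergeticConstants):
    """Glycolytic proton production rate (pmol H+/min).

    ``PPR_glyc = ECAR_tot/BP - OCR_mito * maxH/O2 * 10^(pH-pK1)/(1+10^(pH-pK1))``.
    The subtracted term is acidification from CO2 hydration; at pH = pK1
    the correction factor is exactly 1/2.

    Accepts scalars or arrays. A negative result is returned as-is (it
    signals mis-specified buffering power or constants); callers flag it
    rather than clamping.
    """
    frac = 10.0 ** (k.ph - k.pk1)
    co2_factor = frac / (1.0 + frac)
    return np.asarray(ecar_tot, float) / k.buffering_power - (
        np.asarray(ocr_mito, float) * k.max_h_per_o2 * co2_factor
    )


def compute_atp_rates(ocr_coupled, ocr_mito, ppr_glyc,
                      k: BioenergeticConstants) -> dict:
    """Oxidative and glycolytic ATP production rates (pmol ATP/min).

    Returns a dict with ``atp_ox``, ``atp_glyc`` and their exact sum
    ``atp_total``. Inputs may be scalars or arrays.
    """
    ocr_coupled = np.asarray(ocr_coupled, float)
    ocr_mito = np.asarray(ocr_mito, float)
    ppr_glyc = np.asarray(ppr_glyc, float)
    atp_ox = ocr_coupled * 2.0 * k.po_oxphos + ocr_mito * 2.0 * k.po_tca
    atp_glyc = ppr_glyc * k.atp_per_lactate + ocr_mito * 2.0 * k.po_glyc
    return {"atp_ox": atp_ox, "atp_glyc": atp_glyc, "atp_total": atp_ox + atp_glyc}


def add_atp_rates(summary: pd.DataFrame, k: BioenergeticConstants) -> pd.DataFrame:
    """Append PPR_glyc and ATP-rate columns to a phase summary table.

    Adds ``ppr_glyc``, ``atp_ox``, ``atp_glyc``, ``atp_total`` and a
    boolean ``ppr_negative`` warning flag, plus the constants used as
    table attrs (written alongside CSV output by the CLI).
    """
    out = summary.copy()
    ppr = compute_ppr_glyc(out["ocr_mito"], out["ecar_tot"], k)
    rates = compute_atp_rates(out["ocr_coupled"], out["ocr_mito"], ppr, k)
    out["ppr_glyc"] = ppr
    out["ppr_negative"] = ppr < 0
    for key in ("atp_ox", "atp_glyc", "atp_total"):
        out[key] = rates[key]
    out.attrs["constants"] = k.as_dict()
    return out


#: Columns carrying rate units (divided by the cell-number factor);
#: dimensionless ratios such as src_pct are scale-free and left unchanged.
RATE_COLUMNS = ("ocr_basal", "ocr_post_oligo", "ocr_max", "ocr_rot_aa",
                "ocr_mito", "ocr_coupled", "ocr_leak", "ecar_tot",
                "ppr_glyc", "atp_ox", "atp_glyc", "atp_total")


def normalize_by_signal(results: pd.DataFrame, signal: pd.Series,
                        groups: pd.Series | None = None) -> pd.DataFrame:
    """Normalize per-well rates by a cell-number proxy signal.

    Each rate column is divided by ``signal / mean(signal)``, where the
    mean is taken over the whole plate, or per comparison group when
    ``groups`` is given (both modes exist because normalization against
    a nuclei stain may be applied per well or per group mean). Units are
    preserved.

    Raises
    ------
    NormalizationError
        If any well's signal is nonpositive (names the well).
    """
    signal = signal.reindex(results.index)
    bad = signal.index[~(signal > 0)]
    if len(bad):
        raise NormalizationError(
            f"nonpositive or missing normalization signal for wells: {list(bad)}"
        )
    if groups is None:
        factor = signal / signal.mean()
    else:
        groups = groups.reindex(results.index)
        factor = signal / groups.map(signal.groupby(groups).mean())
    out = results.copy()
    cols = [c for c in RATE_COLUMNS if c in out.columns]
    out[cols] = out[cols].div(factor, axis=0)
    return out
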