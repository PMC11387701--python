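"""Per-measurement radiographic morphological diagnosis.

Each flag traces to exactly one measurement, compared against the commonly
used literature thresholds (inclusive for the printed <= / >= comparators,
strict for the NSA bounds):

- acetabular dysplasia: ADR <= 250, mAI >= 13 deg, WCEA <= 25 deg, EI >= 25 %
- acetabular overcoverage: mAI <= 3 deg
- pincer morphology: LCEA >= 40 deg
- cam morphology: AA >= 60 deg
- coxa valga: NSA > 140 deg; coxa vara: NSA < 120 deg

A missing measurement yields a missing flag (``None``), never a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .morphometry import MeasurementSet

__all__ = [
    "Thresholds",
    "DiagnosisFlags",
    "FLAG_NAMES",
    "FLAG_TO_MEASUREMENT",
    "classify",
    "classify_frame",
    "flags_frame",
    "diagnostic_agreement",
]


@dataclass(frozen=True)
class Thresholds:
    """Diagnostic thresholds; defaults are the standard literature values."""

    adr_max: float = 250.0
    mai_dysplasia_min: float = 13.0
    mai_overcoverage_max: float = 3.0
    wcea_max: float = 25.0
    lcea_min: float = 40.0
    ei_min: float = 25.0
    aa_min: float = 60.0
    nsa_valga_exclusive_min: float = 140.0
    nsa_vara_exclusive_max: float = 120.0

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in raw.items()})

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


FLAG_NAMES = (
    "dysplasia_adr",
    "dysplasia_mai",
    "overcoverage_mai",
    "dysplasia_wcea",
    "pincer_lcea",
    "dysplasia_ei",
    "cam_aa",
    "coxa_valga",
    "coxa_vara",
)

FLAG_TO_MEASUREMENT = {
    "dysplasia_adr": "adr",
    "dysplasia_mai": "mai_deg",
    "overcoverage_mai": "mai_deg",
    "dysplasia_wcea": "wcea_deg",
    "pincer_lcea": "lcea_deg",
    "dysplasia_ei": "ei_pct",
    "cam_aa": "alpha_deg",
    "coxa_valga": "nsa_deg",
    "coxa_vara": "nsa_deg",
}


@dataclass
class DiagnosisFlags:
    """Per-measurement diagnosis booleans; ``None`` when the measurement is missing."""

    dysplasia_adr: Optional[bool] = None
    dysplasia_mai: Optional[bool] = None
    overcoverage_mai: Optional[bool] = None
    dysplasia_wcea: Optional[bool] = None
    pincer_lcea: Optional[bool] = None
    dysplasia_ei: Optional[bool] = None
    cam_aa: Optional[bool] = None
    coxa_valga: Optional[bool] = None
    coxa_vara: Optional[bool] = None
    image_id: str = ""
    side: str = ""

    def as_dict(self) -> dict[str, Optional[bool]]:
        return {name: getattr(self, name) for name in FLAG_NAMES}

    @property
    def any_dysplasia(self) -> Optional[bool]:
        """Convenience any-of-four dysplasia flag (per-measurement flags are primary)."""
        vals = [self.dysplasia_adr, self.dysplasia_mai, self.dysplasia_wcea, self.dysplasia_ei]
        present = [v for v in vals if v is not None]
        if not present:
            return None
        return any(present)


def classify(m: MeasurementSet, thresholds: Thresholds = Thresholds()) -> DiagnosisFlags:
    """Apply the diagnostic thresholds to one measurement set."""
    t = thresholds

    def le(value, bound):
        return None if value is None else bool(value <= bound)

    def ge(value, bound):
        return None if value is None else bool(value >= bound)

    return DiagnosisFlags(
        dysplasia_adr=le(m.adr, t.adr_max),
        dysplasia_mai=ge(m.mai_deg, t.mai_dysplasia_min),
        overcoverage_mai=le(m.mai_deg, t.mai_overcoverage_max),
        dysplasia_wcea=le(m.wcea_deg, t.wcea_max),
        pincer_lcea=ge(m.lcea_deg, t.lcea_min),
        dysplasia_ei=ge(m.ei_pct, t.ei_min),
        cam_aa=ge(m.alpha_deg, t.aa_min),
        coxa_valga=None if m.nsa_deg is None else bool(m.nsa_deg > t.nsa_valga_exclusive_min),
        coxa_vara=None if m.nsa_deg is None else bool(m.nsa_deg < t.nsa_vara_exclusive_max),
        image_id=m.image_id,
        side=m.side,
    )


def classify_frame(
    measurements: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Classify a batch measurements frame (as from ``measurements_frame``)."""
    t = thresholds
    df = pd.DataFrame(index=measurements.index)

    def cmp(series: pd.Series, op, bound) -> pd.Series:
        out = op(series, bound).astype("boolean")
        out[series.isna()] = pd.NA
        return out

    df["dysplasia_adr"] = cmp(measurements["adr"], pd.Series.le, t.adr_max)
    df["dysplasia_mai"] = cmp(measurements["mai_deg"], pd.Series.ge, t.mai_dysplasia_min)
    df["overcoverage_mai"] = cmp(measurements["mai_deg"], pd.Series.le, t.mai_overcoverage_max)
    df["dysplasia_wcea"] = cmp(measurements["wcea_deg"], pd.Series.le, t.wcea_max)
    df["pincer_lcea"] = cmp(measurements["lcea_deg"], pd.Series.ge, t.lcea_min)
    df["dysplasia_ei"] = cmp(measurements["ei_pct"], pd.Series.ge, t.ei_min)
    df["cam_aa"] = cmp(measurements["alpha_deg"], pd.Series.ge, t.aa_min)
    df["coxa_valga"] = cmp(measurements["nsa_deg"], pd.Series.gt, t.nsa_valga_exclusive_min)
    df["coxa_vara"] = cmp(measurements["nsa_deg"], pd.Series.lt, t.nsa_vara_exclusive_max)
    return df


def flags_frame(flags: list[DiagnosisFlags]) -> pd.DataFrame:
    rows = []
    for f in flags:
        row: dict = {"image_id": f.image_id, "side": f.side}
        row.update(f.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows).astype({name: "boolean" for name in FLAG_NAMES})
    if len(df):
        df.index = [f"{r.image_id}:{r.side}" for r in df.itertuples()]
        df.index.name = "hip_id"
    return df


def diagnostic_agreement(a: pd.DataFrame | list, b: pd.DataFrame | list) -> pd.DataFrame:
    """Per-flag percent agreement and prevalence between two aligned flag lists.

    Agreement is 100 * matching non-missing pairs / non-missing pairs;
    prevalence is 100 * positives / non-missing, per source.  A flag with no
    comparable pairs gets NaN agreement and a reason column entry.
    """
    if not isinstance(a, pd.DataFrame):
        a = flags_frame(a)
    if not isinstance(b, pd.DataFrame):
        b = flags_frame(b)
    if len(a) != len(b):
        raise ValueError(f"flag lists differ in length: {len(a)} vs {len(b)}")
    rows = []
    for flag in FLAG_NAMES:
        va, vb = a[flag].to_numpy(), b[flag].to_numpy()
        comparable = pd.notna(va) & pd.notna(vb)
        n = int(comparable.sum())
        if n == 0:
            pct = np.nan
            reason = "no comparable pairs"
        else:
            pct = 100.0 * float((va[comparable] == vb[comparable]).sum()) / n
            reason = ""
        rows.append(
            {
                "flag": flag,
                "percent_agreement": pct,
                "n_comparable": n,
                "prevalence_a": 100.0 * _prevalence(va),
                "prevalence_b": 100.0 * _prevalence(vb),
                "reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("flag")


def _prevalence(values: np.ndarray) -> float:
    present = pd.notna(values)
    if present.sum() == 0:
        return np.nan
    return float((values[present] == True).sum()) / int(present.sum())  # noqa: E712
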