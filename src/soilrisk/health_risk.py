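"""USEPA multi-route human health risk for soil exposure.

Chronic daily intake (CDI, mg/kg/day) is computed for incidental ingestion,
dermal contact and dust inhalation:

    CDI_ingest = CS * IRS * EFr * ED / (BW * AT) * CFu
    CDI_dermal = CS * SA * AF * ABS * EFr * ED / (BW * AT) * CFu
    CDI_inhale = CS * InhR * EFr * ED / (PEF * BW * AT)

with CS the soil concentration (mg/kg), receptor parameters from
:class:`ExposureProfile` and AT the averaging time (365*ED days for
non-carcinogens, 365*70 days for carcinogens). Non-cancer risk is the
hazard quotient HQ = CDI/RfD, summed over routes into the hazard index HI;
cancer risk is CR = CDI * CSF summed into the lifetime cancer risk, judged
against the USEPA acceptable window 1e-6 to 1e-4.

Note the dermal exposure ratio FE is carried in the exposure tables but,
following the printed dose equations, is not applied by default; pass
``use_dermal_exposure_ratio=True`` to include it as a multiplicative factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .core_data import (
    ReferenceSet,
    SampleTable,
    SiteSummary,
    load_packaged_yaml,
    summarize_by_site,
)

__all__ = [
    "ROUTES",
    "ExposureProfile",
    "ToxicityTable",
    "cdi_ingestion",
    "cdi_dermal",
    "cdi_inhalation",
    "chronic_daily_intake",
    "hazard_quotient",
    "hazard_index",
    "cancer_risk",
    "lifetime_cancer_risk",
    "cancer_risk_flag",
    "RiskReport",
    "assess_health_risk",
]

ROUTES: tuple[str, ...] = ("ingestion", "dermal", "inhalation")

#: USEPA acceptable incremental cancer-risk window.
CANCER_RISK_LOW = 1e-6
CANCER_RISK_HIGH = 1e-4


@dataclass(frozen=True)
class ExposureProfile:
    """Receptor-specific exposure parameters (units in ``exposure.yaml``)."""

    receptor: str
    body_weight: float
    exposure_frequency: float
    exposure_duration: float
    ingestion_rate: float
    inhalation_rate: float
    skin_area: float
    adherence_factor: float
    dermal_absorption: float
    dermal_exposure_ratio: float
    particulate_emission_factor: float
    conversion_factor: float = 1e-6
    lifetime_years: float = 70.0

    def averaging_time(self, carcinogenic: bool) -> float:
        """Averaging time in days: 365*lifetime for carcinogens, 365*ED else."""
        years = self.lifetime_years if carcinogenic else self.exposure_duration
        return 365.0 * years

    @classmethod
    def from_mapping(cls, receptor: str, params: Mapping[str, float]) -> "ExposureProfile":
        return cls(receptor=receptor, **{k: float(v) for k, v in params.items()})


def _load_profiles(path: str | Path | None = None) -> dict[str, ExposureProfile]:
    raw = (
        load_packaged_yaml("exposure.yaml")
        if path is None
        else yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    )
    return {name: ExposureProfile.from_mapping(name, params) for name, params in raw.items()}


_DEFAULT_PROFILES = _load_profiles()
CHILD: ExposureProfile = _DEFAULT_PROFILES["child"]
ADULT: ExposureProfile = _DEFAULT_PROFILES["adult"]


def load_exposure_profiles(path: str | Path | None = None) -> dict[str, ExposureProfile]:
    """Receptor name -> profile, from YAML (packaged defaults if no path)."""
    return _load_profiles(path)


# ---------------------------------------------------------------------------
# Dose equations


def _check_cs(cs: float) -> None:
    if cs < 0:
        raise ValueError(f"soil concentration must be non-negative, got {cs}")


def cdi_ingestion(cs: float, profile: ExposureProfile, carcinogenic: bool = False) -> float:
    """Chronic daily intake via incidental soil ingestion (mg/kg/day)."""
    _check_cs(cs)
    at = profile.averaging_time(carcinogenic)
    return (
        cs
        * profile.ingestion_rate
        * profile.exposure_frequency
        * profile.exposure_duration
        / (profile.body_weight * at)
        * profile.conversion_factor
    )


def cdi_dermal(
    cs: float,
    profile: ExposureProfile,
    carcinogenic: bool = False,
    *,
    use_dermal_exposure_ratio: bool = False,
) -> float:
    """Chronic daily intake via dermal contact with soil (mg/kg/day)."""
    _check_cs(cs)
    at = profile.averaging_time(carcinogenic)
    dose = (
        cs
        * profile.skin_area
        * profile.adherence_factor
        * profile.dermal_absorption
        * profile.exposure_frequency
        * profile.exposure_duration
        / (profile.body_weight * at)
        * profile.conversion_factor
    )
    if use_dermal_exposure_ratio:
        dose *= profile.dermal_exposure_ratio
    return dose


def cdi_inhalation(cs: float, profile: ExposureProfile, carcinogenic: bool = False) -> float:
    """Chronic daily intake via inhalation of soil dust (mg/kg/day).

    The particulate emission factor converts soil to air concentration, so
    no kg/mg conversion factor appears.
    """
    _check_cs(cs)
    at = profile.averaging_time(carcinogenic)
    return (
        cs
        * profile.inhalation_rate
        * profile.exposure_frequency
        * profile.exposure_duration
        / (profile.particulate_emission_factor * profile.body_weight * at)
    )


def chronic_daily_intake(
    cs: float,
    profile: ExposureProfile,
    route: str,
    carcinogenic: bool = False,
    **kwargs,
) -> float:
    """Dispatch to the route-specific CDI equation."""
    if route == "ingestion":
        return cdi_ingestion(cs, profile, carcinogenic)
    if route == "dermal":
        return cdi_dermal(cs, profile, carcinogenic, **kwargs)
    if route == "inhalation":
        return cdi_inhalation(cs, profile, carcinogenic)
    raise KeyError(f"unknown exposure route {route!r} (expected one of {ROUTES})")


# ---------------------------------------------------------------------------
# Toxicity constants


@dataclass(frozen=True)
class ToxicityTable:
    """Route-specific RfD and CSF values with oral fallback.

    Querying an undefined (element, route) pair returns ``None`` — an
    explicit "not assessed" outcome, never zero. Where only the oral value
    is configured, dermal and inhalation fall back to it (flagged); a
    gastrointestinal absorption fraction, when provided for an element,
    scales the dermal fallback (RfD_dermal = RfD_oral * GIABS).
    """

    rfd: Mapping[str, Mapping[str, float]]
    csf: Mapping[str, Mapping[str, float]]
    gi_absorption: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table, name in ((self.rfd, "RfD"), (self.csf, "CSF")):
            for e, routes in table.items():
                for r, v in routes.items():
                    if not v > 0:
                        raise ValueError(f"{name} for {e}/{r} must be positive, got {v}")

    def _lookup(
        self, table: Mapping[str, Mapping[str, float]], element: str, route: str,
        dermal_gi: bool,
    ) -> tuple[float, bool] | None:
        routes = table.get(element)
        if not routes:
            return None
        if route in routes:
            return float(routes[route]), False
        if "ingestion" in routes:
            value = float(routes["ingestion"])
            if dermal_gi and route == "dermal" and element in self.gi_absorption:
                value *= float(self.gi_absorption[element])
            return value, True
        return None

    def rfd_for(self, element: str, route: str) -> tuple[float, bool] | None:
        """(RfD, oral-fallback flag) or None if the pair is not assessed."""
        return self._lookup(self.rfd, element, route, dermal_gi=True)

    def csf_for(self, element: str, route: str) -> tuple[float, bool] | None:
        """(CSF, oral-fallback flag) or None for non-carcinogens."""
        return self._lookup(self.csf, element, route, dermal_gi=False)

    @classmethod
    def default(cls) -> "ToxicityTable":
        raw = load_packaged_yaml("toxicity.yaml")
        return cls(rfd=raw["rfd"], csf=raw["csf"], gi_absorption=raw.get("gi_absorption", {}))

    @classmethod
    def from_file(cls, path: str | Path) -> "ToxicityTable":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            rfd=raw.get("rfd", {}),
            csf=raw.get("csf", {}),
            gi_absorption=raw.get("gi_absorption", {}),
        )


# ---------------------------------------------------------------------------
# Risk quotients


def hazard_quotient(cdi: float, rfd: float) -> float:
    """HQ = CDI / RfD; unity marks the USEPA non-cancer threshold."""
    if not rfd > 0:
        raise ValueError(f"reference dose must be positive, got {rfd}")
    return cdi / rfd


def hazard_index(hq_values: Iterable[float | None]) -> float:
    """HI = sum of defined HQs; raises if every route is undefined."""
    vals = [v for v in hq_values if v is not None]
    if not vals:
        raise ValueError("hazard index requires at least one defined HQ")
    return float(sum(vals))


def cancer_risk(cdi_carcinogenic: float, csf: float) -> float:
    """CR = carcinogenic-averaged CDI times the cancer slope factor."""
    if not csf > 0:
        raise ValueError(f"cancer slope factor must be positive, got {csf}")
    return cdi_carcinogenic * csf


def lifetime_cancer_risk(cr_values: Iterable[float | None]) -> float:
    """Route-summed lifetime cancer risk over the defined routes."""
    vals = [v for v in cr_values if v is not None]
    if not vals:
        raise ValueError("lifetime cancer risk requires at least one defined CR")
    return float(sum(vals))


def cancer_risk_flag(cr: float) -> str:
    """Judge a cancer risk against the 1e-6..1e-4 acceptable window."""
    if cr > CANCER_RISK_HIGH:
        return "exceeds"
    if cr < CANCER_RISK_LOW:
        return "negligible"
    return "acceptable"


# ---------------------------------------------------------------------------
# Site-level assessment


@dataclass
class RiskReport:
    """Long-format per-route detail plus per-site HI / LTCR summary.

    ``detail`` columns: receptor, land_use, element, route, cdi, hq, cr,
    rfd_fallback. ``notes`` records (element, route) pairs excluded as not
    assessed.
    """

    detail: pd.DataFrame
    notes: list[str]

    def hi(self, receptor: str, land_use: str, element: str | None = None) -> float:
        """Route-summed HI for one element, or site HI over all elements."""
        block = self.detail[
            (self.detail.receptor == receptor) & (self.detail.land_use == land_use)
        ]
        if element is not None:
            block = block[block.element == element]
        return hazard_index(block.hq.tolist())

    def ltcr(self, receptor: str, land_use: str, element: str | None = None) -> float:
        block = self.detail[
            (self.detail.receptor == receptor) & (self.detail.land_use == land_use)
        ]
        if element is not None:
            block = block[block.element == element]
        return lifetime_cancer_risk(block.cr.tolist())

    def summary(self) -> pd.DataFrame:
        """Per (receptor, land_use): HI and LTCR totals with window flags."""
        rows = []
        for (receptor, land_use), block in self.detail.groupby(
            ["receptor", "land_use"], sort=False
        ):
            hi_total = hazard_index(block.hq.tolist())
            crs = [v for v in block.cr.tolist() if v is not None]
            ltcr_total = float(sum(crs)) if crs else float("nan")
            rows.append(
                {
                    "receptor": receptor,
                    "land_use": land_use,
                    "hi_total": hi_total,
                    "hi_flag": "concern" if hi_total > 1 else "below threshold",
                    "ltcr_total": ltcr_total,
                    "ltcr_flag": cancer_risk_flag(ltcr_total) if crs else "not assessed",
                }
            )
        return pd.DataFrame(rows)


def assess_health_risk(
    data: SampleTable | Sequence[SiteSummary],
    *,
    profiles: Sequence[ExposureProfile] = (CHILD, ADULT),
    toxicity: ToxicityTable | None = None,
    use_dermal_exposure_ratio: bool = False,
) -> RiskReport:
    """Full CDI -> HQ/HI and CDI -> CR/LTCR chain at site-mean concentrations.

    Site means are the default exposure-point concentrations (matching how
    survey reports chain site statistics into risk); pass a single-site
    summary list for per-sample work.
    """
    toxicity = toxicity or ToxicityTable.default()
    summaries = summarize_by_site(data) if isinstance(data, SampleTable) else data
    rows = []
    notes: list[str] = []
    for profile in profiles:
        for s in summaries:
            for element, cs in s.mean.items():
                rfd_missing_everywhere = True
                for route in ROUTES:
                    kwargs = (
                        {"use_dermal_exposure_ratio": use_dermal_exposure_ratio}
                        if route == "dermal"
                        else {}
                    )
                    cdi_nc = chronic_daily_intake(cs, profile, route, False, **kwargs)
                    cdi_ca = chronic_daily_intake(cs, profile, route, True, **kwargs)
                    rfd_entry = toxicity.rfd_for(element, route)
                    if rfd_entry is None:
                        hq = None
                        fallback = False
                        notes.append(
                            f"{element}/{route}: no RfD configured; excluded from HI"
                        )
                    else:
                        rfd, fallback = rfd_entry
                        hq = hazard_quotient(cdi_nc, rfd)
                    csf_entry = toxicity.csf_for(element, route)
                    if csf_entry is None:
                        cr = None
                    else:
                        cr = cancer_risk(cdi_ca, csf_entry[0])
                    rows.append(
                        {
                            "receptor": profile.receptor,
                            "land_use": s.land_use,
                            "element": element,
                            "route": route,
                            "cdi": cdi_nc,
                            "cdi_carcinogenic": cdi_ca,
                            "hq": hq,
                            "cr": cr,
                            "rfd_fallback": fallback,
                        }
                    )
                    if rfd_entry is not None:
                        rfd_missing_everywhere = False
                if rfd_missing_everywhere:
                    notes.append(
                        f"{element}: not assessed for non-carcinogenic risk"
                    )
    return RiskReport(detail=pd.DataFrame(rows), notes=sorted(set(notes)))
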