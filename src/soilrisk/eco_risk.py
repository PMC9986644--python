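"""Hakanson potential ecological risk.

Each element's risk factor is its contamination factor weighted by a
biological toxic-response factor, ``E_r = T_r * CF``; the site-level index
sums them, ``PERI = sum(E_r)``. Cd (T_r = 30) dominates the weighting, which
is why Cd-enriched urban soils score high even at modest concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_data import ReferenceSet, SampleTable, SiteSummary, summarize_by_site
from .indices import Scheme, _SCHEMES, classify_index, contamination_factor

__all__ = [
    "ecological_risk_factor",
    "potential_ecological_risk",
    "classify_eco_risk",
    "EcoRiskReport",
    "site_eco_risk",
]


def ecological_risk_factor(cf: float, toxic_response: float) -> float:
    """E_r = toxic-response factor times contamination factor."""
    if cf < 0:
        raise ValueError(f"contamination factor must be non-negative, got {cf}")
    if not toxic_response > 0:
        raise ValueError(
            f"toxic-response factor must be positive, got {toxic_response}"
        )
    return toxic_response * cf


def potential_ecological_risk(e_r_values: Iterable[float]) -> float:
    """PERI = sum of the per-element ecological risk factors."""
    vals = list(e_r_values)
    if not vals:
        raise ValueError("PERI requires at least one E_r value")
    return float(sum(vals))


def classify_eco_risk(
    value: float,
    scheme: str = "peri_study",
    schemes: Mapping[str, Scheme] | None = None,
) -> str:
    """Label a PERI (or E_r, with ``scheme="er_hakanson"``) value."""
    return classify_index(value, scheme, schemes)


@dataclass(frozen=True)
class EcoRiskReport:
    """Per-land-use ecological risk: E_r per element, PERI and its label."""

    land_use: str
    e_r: Mapping[str, float]
    peri: float
    risk_level: str
    e_r_level: Mapping[str, str]


def site_eco_risk(
    data: SampleTable | Sequence[SiteSummary],
    refs: ReferenceSet,
    *,
    peri_scheme: str = "peri_study",
    er_scheme: str = "er_hakanson",
    schemes: Mapping[str, Scheme] | None = None,
) -> list[EcoRiskReport]:
    """E_r and PERI per land use from site-mean concentrations.

    The default PERI scheme is the survey-reconstructed one; pass
    ``peri_scheme="peri_hakanson"`` for the classical 150/300/600 cutoffs.
    """
    summaries = summarize_by_site(data) if isinstance(data, SampleTable) else data
    reports = []
    for s in summaries:
        elements = list(s.mean)
        refs.require_elements(elements)
        e_r = {
            e: ecological_risk_factor(
                contamination_factor(s.mean[e], refs.background[e]),
                refs.toxic_response[e],
            )
            for e in elements
        }
        peri = potential_ecological_risk(e_r.values())
        reports.append(
            EcoRiskReport(
                land_use=s.land_use,
                e_r=e_r,
                peri=peri,
                risk_level=classify_index(peri, peri_scheme, schemes),
                e_r_level={
                    e: classify_index(v, er_scheme, schemes) for e, v in e_r.items()
                },
            )
        )
    return reports


def eco_risk_frame(reports: Sequence[EcoRiskReport]) -> pd.DataFrame:
    """Flatten eco-risk reports to one row per land use."""
    rows = []
    for r in reports:
        row: dict = {"land_use": r.land_use}
        row.update({f"er_{e}": v for e, v in r.e_r.items()})
        row["peri"] = r.peri
        row["risk_level"] = r.risk_level
        rows.append(row)
    return pd.DataFrame(rows).set_index("land_use")


def peri_ranking(reports: Sequence[EcoRiskReport]) -> list[str]:
    """Land-use codes in descending PERI order."""
    return [r.land_use for r in sorted(reports, key=lambda r: r.peri, reverse=True)]
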