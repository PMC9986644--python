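"""Pollution indices for potentially toxic elements in soil.

Implements the standard index battery used in soil-contamination surveys:

- contamination factor ``CF = C / B`` (sample over geochemical background),
- degree of contamination ``C_d = sum(CF)`` over the studied elements,
- enrichment factor ``EF = (C/Fe)_sample / (B/Fe_B)_background`` (iron
  double-normalisation to control for crustal variability),
- Muller geoaccumulation index ``Igeo = log2(C / (1.5 B))``,
- pollution load index ``PLI = (CF_1 ... CF_n)^(1/n)`` (geometric mean),

plus data-driven category labelling. Category schemes are data, not code:
``schemes.yaml`` ships the classical Hakanson/Muller cutoffs alongside
``cd_study``/``peri_study`` schemes reconstructed from the Jashore survey's
printed labels (which are inconsistent with the classical bounds).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    ReferenceSet,
    SampleTable,
    SiteSummary,
    ValidationError,
    load_packaged_yaml,
    site_mean_frame,
    summarize_by_site,
)

__all__ = [
    "Scheme",
    "load_schemes",
    "classify_index",
    "contamination_factor",
    "degree_of_contamination",
    "enrichment_factor",
    "geoaccumulation_index",
    "pollution_load_index",
    "IndexReport",
    "site_indices",
]


# ---------------------------------------------------------------------------
# Classification schemes


@dataclass(frozen=True)
class Scheme:
    """Ordered, lower-inclusive bins covering ``[lower, inf)``."""

    name: str
    lower: float
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError(
                f"scheme {self.name}: need one more label than boundaries"
            )
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValueError(f"scheme {self.name}: boundaries must be increasing")

    def classify(self, value: float) -> str:
        if math.isnan(value):
            raise ValueError(f"cannot classify NaN under scheme {self.name}")
        if value < self.lower:
            raise ValueError(
                f"value {value} below the domain of scheme {self.name} "
                f"(lower bound {self.lower})"
            )
        # lower-inclusive: a value equal to a boundary falls in the upper bin
        return self.labels[bisect_right(self.boundaries, value)]


def load_schemes(path: str | None = None) -> dict[str, Scheme]:
    """Load classification schemes from YAML (packaged defaults if no path)."""
    if path is None:
        raw = load_packaged_yaml("schemes.yaml")
    else:
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    out = {}
    for name, entry in raw.items():
        out[name] = Scheme(
            name=name,
            lower=float(entry.get("lower", 0.0)),
            boundaries=tuple(float(b) for b in entry["boundaries"]),
            labels=tuple(entry["labels"]),
        )
    return out


_SCHEMES = load_schemes()


def classify_index(
    value: float, index_name: str, scheme: Scheme | Mapping[str, Scheme] | None = None
) -> str:
    """Label a value under a named scheme (e.g. ``"cd_study"``)."""
    if isinstance(scheme, Scheme):
        return scheme.classify(value)
    table = scheme if scheme is not None else _SCHEMES
    if index_name not in table:
        raise KeyError(
            f"unknown scheme {index_name!r} (available: {', '.join(table)})"
        )
    return table[index_name].classify(value)


# ---------------------------------------------------------------------------
# Scalar indices


def contamination_factor(conc: float, background: float) -> float:
    """CF = concentration over geochemical background."""
    if not background > 0:
        raise ValueError(f"background must be positive, got {background}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    return conc / background


def degree_of_contamination(cf_values: Iterable[float]) -> float:
    """C_d = sum of the per-element contamination factors."""
    vals = list(cf_values)
    if not vals:
        raise ValueError("degree of contamination requires at least one CF")
    return float(sum(vals))


def enrichment_factor(
    conc: float, fe_sample: float, background: float, fe_background: float
) -> float:
    """EF = (C/Fe)_sample over (B/Fe)_background."""
    for name, v in (
        ("fe_sample", fe_sample),
        ("background", background),
        ("fe_background", fe_background),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (conc / fe_sample) / (background / fe_background)


def geoaccumulation_index(
    conc: float, background: float, *, zero_conc: str = "error"
) -> float:
    """Igeo = log2(C / (1.5 B)); the 1.5 buffers natural background spread.

    ``zero_conc`` selects the behaviour at C = 0: ``"error"`` (default —
    real soils are never exactly zero) or ``"neginf"`` for a -inf sentinel.
    """
    if not background > 0:
        raise ValueError(f"background must be positive, got {background}")
    if conc < 0:
        raise ValueError(f"concentration must be non-negative, got {conc}")
    if conc == 0:
        if zero_conc == "neginf":
            return float("-inf")
        raise ValueError("Igeo undefined for zero concentration")
    return math.log2(conc / (1.5 * background))


def pollution_load_index(cf_values: Iterable[float]) -> float:
    """PLI = geometric mean of the contamination factors."""
    vals = np.asarray(list(cf_values), dtype=float)
    if vals.size == 0:
        raise ValueError("pollution load index requires at least one CF")
    if (vals <= 0).any():
        raise ValueError("pollution load index requires strictly positive CFs")
    return float(np.exp(np.log(vals).mean()))


# ---------------------------------------------------------------------------
# Site-level reports


@dataclass(frozen=True)
class IndexReport:
    """Per-land-use index bundle with category labels."""

    land_use: str
    cf: Mapping[str, float]
    c_d: float
    igeo: Mapping[str, float]
    pli: float
    ef: Mapping[str, float] | None
    category: Mapping[str, str]


def site_indices(
    data: SampleTable | Sequence[SiteSummary],
    refs: ReferenceSet,
    *,
    cd_scheme: str = "cd_study",
    schemes: Mapping[str, Scheme] | None = None,
    pli_basis: str = "site_mean",
) -> list[IndexReport]:
    """CF/C_d/Igeo/PLI per land use from site-mean concentrations.

    ``pli_basis``: ``"site_mean"`` computes the PLI from site-mean CFs
    (default — matches how survey tables chain site means into indices);
    ``"per_sample"`` averages per-sample PLIs instead (SampleTable input
    only).
    """
    if pli_basis not in ("site_mean", "per_sample"):
        raise ValueError(f"unknown PLI basis {pli_basis!r}")
    if isinstance(data, SampleTable):
        summaries = summarize_by_site(data)
        samples: SampleTable | None = data
    else:
        summaries = list(data)
        samples = None
        if pli_basis == "per_sample":
            raise ValueError("per-sample PLI needs a SampleTable input")
    table = schemes if schemes is not None else _SCHEMES
    reports = []
    for s in summaries:
        elements = list(s.mean)
        refs.require_elements(elements)
        cf = {e: contamination_factor(s.mean[e], refs.background[e]) for e in elements}
        igeo = {
            e: geoaccumulation_index(s.mean[e], refs.background[e]) for e in elements
        }
        if pli_basis == "site_mean":
            pli = pollution_load_index(cf.values())
        else:
            block = samples.data[samples.land_use == s.land_use]
            pli = float(
                np.mean(
                    [
                        pollution_load_index(
                            contamination_factor(row[e], refs.background[e])
                            for e in elements
                        )
                        for _, row in block.iterrows()
                    ]
                )
            )
        c_d = degree_of_contamination(cf.values())
        category = {
            "c_d": classify_index(c_d, cd_scheme, table),
            "pli": classify_index(pli, "pli", table),
        }
        reports.append(
            IndexReport(
                land_use=s.land_use,
                cf=cf,
                c_d=c_d,
                igeo=igeo,
                pli=pli,
                ef=None,
                category=category,
            )
        )
    return reports


def index_frame(reports: Sequence[IndexReport]) -> pd.DataFrame:
    """Flatten index reports to one row per land use."""
    rows = []
    for r in reports:
        row: dict = {"land_use": r.land_use}
        row.update({f"cf_{e}": v for e, v in r.cf.items()})
        row["c_d"] = r.c_d
        row.update({f"igeo_{e}": v for e, v in r.igeo.items()})
        row["pli"] = r.pli
        row["c_d_level"] = r.category["c_d"]
        row["pli_level"] = r.category["pli"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("land_use")
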