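"""Domain types, reference tables and tabular I/O shared by all pipeline stages.

The universal input is a :class:`SampleTable` — one row per composite soil
sample, with a land-use code and total concentrations (mg/kg dry weight) of
the monitored potentially toxic elements (As, Cd, Pb, Cr, Ni, Cu, optionally
Fe for enrichment-factor normalisation). Reference quantities (geochemical
backgrounds, Hakanson toxic-response factors, regulatory standards) live in a
:class:`ReferenceSet`; the shipped defaults describe the Jashore district
(Bangladesh) urban-soil survey area.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: Elements the shipped reference tables cover, in conventional order.
ELEMENTS: tuple[str, ...] = ("As", "Cd", "Pb", "Cr", "Ni", "Cu")

#: Registered land-use codes: park area, playground, market, brickfield,
#: industrial area, petrol pump, metal workshop, bus stand, power station,
#: residential area, waste dumping area.
LAND_USES: tuple[str, ...] = (
    "PA", "PG", "M", "BF", "IA", "PP", "MW", "BS", "PS", "RA", "WDA",
)

LAND_USE_NAMES: dict[str, str] = {
    "PA": "park area",
    "PG": "playground",
    "M": "market",
    "BF": "brickfield",
    "IA": "industrial area",
    "PP": "petrol pump",
    "MW": "metal workshop",
    "BS": "bus stand",
    "PS": "power station",
    "RA": "residential area",
    "WDA": "waste dumping area",
}


class ValidationError(ValueError):
    """Raised when an input table or reference set violates an invariant."""


def _data_path(name: str):
    return resources.files("soilrisk.data").joinpath(name)


def load_packaged_yaml(name: str) -> dict:
    with _data_path(name).open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_packaged_csv(name: str, **kwargs) -> pd.DataFrame:
    with _data_path(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#", **kwargs)


# ---------------------------------------------------------------------------
# SampleTable


@dataclass
class SampleTable:
    """Validated per-sample concentration table.

    Parameters
    ----------
    data:
        One row per sample with columns ``sample_id``, ``land_use``, one
        column per element (mg/kg dry weight) and optionally ``Fe``.
    below_detection:
        Optional boolean frame (same index, element columns) flagging cells
        reported below the method detection limit. Flagged cells hold the
        substitution value (MDL/2 by default) in ``data``.
    mdl:
        Per-element method detection limits (mg/kg); required for any
        element with a flagged cell and by the PMF uncertainty rules.
    """

    data: pd.DataFrame
    below_detection: pd.DataFrame | None = None
    mdl: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        for col in ("sample_id", "land_use"):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        if not self.elements:
            raise ValidationError("no element concentration columns found")
        df["land_use"] = df["land_use"].astype(str).str.upper()
        bad = ~df["land_use"].isin(LAND_USES)
        if bad.any():
            row = df.index[bad][0]
            code = df.loc[row, "land_use"]
            raise ValidationError(
                f"unknown land-use code {code!r} in row {row!r} "
                f"(registered codes: {', '.join(LAND_USES)})"
            )
        conc_cols = list(self.elements) + (["Fe"] if "Fe" in df.columns else [])
        for col in conc_cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = df.index[vals.isna()][0]
                raise ValidationError(f"non-numeric {col} concentration in row {row!r}")
            if (vals < 0).any():
                row = df.index[vals < 0][0]
                raise ValidationError(
                    f"negative {col} concentration in row "
                    f"{df.loc[row, 'sample_id']!r}"
                )
            df[col] = vals.astype(float)
        if self.below_detection is not None:
            flagged = [e for e in self.elements if self.below_detection[e].any()]
            for e in flagged:
                if self.mdl.get(e, 0.0) <= 0:
                    raise ValidationError(
                        f"below-detection cells for {e} require a positive MDL"
                    )

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(e for e in ELEMENTS if e in self.data.columns)

    @property
    def n(self) -> int:
        return len(self.data)

    def concentrations(self, elements: Sequence[str] | None = None) -> pd.DataFrame:
        """Element concentration block (samples x elements)."""
        cols = list(elements) if elements is not None else list(self.elements)
        return self.data[cols].copy()

    @property
    def land_use(self) -> pd.Series:
        return self.data["land_use"]


def read_sample_table(
    path: str | Path,
    *,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
    mdl: Mapping[str, float] | None = None,
    bd_policy: str = "half_mdl",
) -> SampleTable:
    """Read and validate a delimited sample table.

    Below-detection cells use the ``"<value"`` sentinel convention (e.g.
    ``<0.004``); the numeric part is taken as the MDL and the working
    concentration follows ``bd_policy``: ``"half_mdl"`` (default, MDL/2),
    ``"mdl"`` or ``"zero"``. An explicit ``mdl`` mapping overrides the
    sentinel-derived limits.
    """
    if bd_policy not in ("half_mdl", "mdl", "zero"):
        raise ValueError(f"unknown below-detection policy {bd_policy!r}")
    raw = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    for col in ("sample_id", "land_use"):
        if col not in raw.columns:
            raise ValidationError(f"input file lacks required column {col!r}")
    elements = [e for e in ELEMENTS if e in raw.columns]
    if not elements:
        raise ValidationError(
            "input file names no element columns "
            f"(expected some of: {', '.join(ELEMENTS)})"
        )
    mdl_out: dict[str, float] = dict(mdl or {})
    factor = {"half_mdl": 0.5, "mdl": 1.0, "zero": 0.0}[bd_policy]
    flags = pd.DataFrame(False, index=raw.index, columns=elements)
    conc_cols = elements + (["Fe"] if "Fe" in raw.columns else [])
    for col in conc_cols:
        cells = raw[col].astype(str).str.strip()
        below = cells.str.startswith("<")
        if below.any() and col in elements:
            limits = pd.to_numeric(cells[below].str.lstrip("<"), errors="coerce")
            if limits.isna().any() or (limits <= 0).any():
                row = limits.index[limits.isna() | (limits <= 0)][0]
                raise ValidationError(
                    f"unparseable below-detection sentinel in column {col}, row {row}"
                )
            limit = float(mdl_out.get(col, limits.max()))
            mdl_out.setdefault(col, limit)
            flags.loc[below, col] = True
            cells = cells.copy()
            cells[below] = str(limit * factor)
        raw[col] = cells
    table = SampleTable(
        data=raw[["sample_id", "land_use"] + conc_cols].copy(),
        below_detection=flags if flags.any().any() else None,
        mdl=mdl_out,
    )
    return table


def write_sample_table(table: SampleTable, path: str | Path, *, sep: str = ",") -> None:
    """Write a sample table; below-detection cells render as ``<MDL``."""
    out = table.data.copy()
    if table.below_detection is not None:
        for e in table.elements:
            mask = table.below_detection[e]
            if mask.any():
                out[e] = out[e].astype(object)
                out.loc[mask, e] = f"<{table.mdl[e]:g}"
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ReferenceSet


@dataclass(frozen=True)
class ReferenceSet:
    """Background concentrations, toxic-response factors and standards.

    ``background`` and the per-standard values are mg/kg dry weight;
    ``toxic_response`` holds the dimensionless Hakanson factors. The
    defaults are the survey-area backgrounds (As 4.90, Cd 0.30, Pb 20.00,
    Cr 41.00, Ni 22.00, Cu 27.00) with T_r = {As 10, Cd 30, Pb 5, Cr 2,
    Ni 6, Cu 5} and the DSQS/CSQS/TRV/ASQS standards tables.
    """

    background: Mapping[str, float]
    toxic_response: Mapping[str, float]
    standards: Mapping[str, Mapping[str, float]]
    fe_background: float | None = None

    def __post_init__(self) -> None:
        for e, v in self.background.items():
            if not v > 0:
                raise ValidationError(f"background for {e} must be positive, got {v}")
        for e, v in self.toxic_response.items():
            if not v > 0:
                raise ValidationError(
                    f"toxic-response factor for {e} must be positive, got {v}"
                )
        if self.fe_background is not None and not self.fe_background > 0:
            raise ValidationError("Fe background must be positive when given")

    @classmethod
    def default(cls) -> "ReferenceSet":
        bg = load_packaged_csv("backgrounds.csv").set_index("element")["background"]
        tr = load_packaged_csv("toxic_response.csv").set_index("element")[
            "toxic_response"
        ]
        std = load_packaged_csv("standards.csv").set_index("standard")
        return cls(
            background=bg.to_dict(),
            toxic_response=tr.astype(float).to_dict(),
            standards={name: row.to_dict() for name, row in std.iterrows()},
        )

    @classmethod
    def from_files(
        cls,
        background_path: str | Path,
        toxic_response_path: str | Path | None = None,
        standards_path: str | Path | None = None,
        fe_background: float | None = None,
    ) -> "ReferenceSet":
        bg = pd.read_csv(background_path, comment="#").set_index("element")[
            "background"
        ]
        default = cls.default()
        tr = (
            pd.read_csv(toxic_response_path, comment="#")
            .set_index("element")["toxic_response"]
            .to_dict()
            if toxic_response_path
            else default.toxic_response
        )
        std = (
            {
                name: row.to_dict()
                for name, row in pd.read_csv(standards_path, comment="#")
                .set_index("standard")
                .iterrows()
            }
            if standards_path
            else default.standards
        )
        return cls(
            background=bg.to_dict(),
            toxic_response=tr,
            standards=std,
            fe_background=fe_background,
        )

    def require_elements(self, elements: Iterable[str]) -> None:
        """Abort with the missing element named if references are incomplete."""
        for e in elements:
            if e not in self.background:
                raise ValidationError(f"reference set lacks a background for {e}")
            if e not in self.toxic_response:
                raise ValidationError(
                    f"reference set lacks a toxic-response factor for {e}"
                )


# ---------------------------------------------------------------------------
# SiteSummary


@dataclass(frozen=True)
class SiteSummary:
    """Per-land-use mean/SD/range statistics for each element (mg/kg)."""

    land_use: str
    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]
    min: Mapping[str, float]
    max: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("site summary requires n >= 1")
        for e in self.mean:
            lo, mu, hi = self.min[e], self.mean[e], self.max[e]
            if not (lo <= mu <= hi) or math.isnan(mu):
                raise ValidationError(
                    f"inconsistent summary for {self.land_use}/{e}: "
                    f"min {lo}, mean {mu}, max {hi}"
                )
            if self.sd[e] < 0:
                raise ValidationError(f"negative SD for {self.land_use}/{e}")


def summarize_by_site(samples: SampleTable) -> list[SiteSummary]:
    """Per-land-use mean, sample SD (n-1), min and max for each element.

    Single-sample sites report SD = 0.
    """
    out: list[SiteSummary] = []
    elements = list(samples.elements)
    for code in LAND_USES:
        block = samples.data[samples.land_use == code]
        if block.empty:
            continue
        conc = block[elements]
        sd = conc.std(ddof=1).fillna(0.0)
        out.append(
            SiteSummary(
                land_use=code,
                n=len(block),
                mean=conc.mean().to_dict(),
                sd=sd.to_dict(),
                min=conc.min().to_dict(),
                max=conc.max().to_dict(),
            )
        )
    return out


def site_mean_frame(summaries: Sequence[SiteSummary]) -> pd.DataFrame:
    """Site-by-element mean concentrations as a DataFrame (land_use index)."""
    rows = {s.land_use: s.mean for s in summaries}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "land_use"
    return df


def reference_site_summaries() -> list[SiteSummary]:
    """The shipped survey statistics (11 land uses, 71 samples) as summaries."""
    spec = load_packaged_yaml("site_specs.yaml")["sites"]
    out = []
    for code, entry in spec.items():
        elems = {k: v for k, v in entry.items() if k != "n"}
        out.append(
            SiteSummary(
                land_use=code,
                n=int(entry["n"]),
                mean={e: p["mean"] for e, p in elems.items()},
                sd={e: p["sd"] for e, p in elems.items()},
                min={e: p["lower"] for e, p in elems.items()},
                max={e: p["upper"] for e, p in elems.items()},
            )
        )
    return out


def exceedance_fraction(
    samples: SampleTable,
    refs: ReferenceSet,
    standard: str,
    element: str,
) -> float:
    """Fraction of samples whose concentration exceeds a standard value."""
    if standard not in refs.standards:
        raise KeyError(
            f"unknown standard {standard!r} "
            f"(available: {', '.join(refs.standards)})"
        )
    if element not in refs.standards[standard]:
        raise KeyError(f"standard {standard} defines no value for {element!r}")
    if element not in samples.elements:
        raise KeyError(f"sample table has no {element} column")
    limit = float(refs.standards[standard][element])
    return float((samples.data[element] > limit).mean())
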