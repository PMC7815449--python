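"""Annotation-stage utilities and the end-to-end report.

Covers the content-analysis side of the study design: chance-corrected
intercoder agreement (Krippendorff's alpha, nominal level) on a systematic
reliability subsample, the half-up percentage rounding used in the printed
tables, and an orchestrator that runs every stage — stance recoding, global
network statistics, category composition, network exposure to antivaccine
videos, and the per-type odds-ratio table — over a collection of networks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import casecontrol, exposure, netstats
from .graph_core import RecNetwork, recode_stance

logger = logging.getLogger(__name__)

__all__ = [
    "RatingsMatrix",
    "ReportBundle",
    "krippendorff_alpha",
    "systematic_sample",
    "pct",
    "run_report",
    "OR_TYPES",
]


# ---------------------------------------------------------------------------
# Intercoder reliability
# ---------------------------------------------------------------------------


@dataclass
class RatingsMatrix:
    """Nominal codes assigned by multiple coders to multiple units.

    ``ratings`` maps (coder, unit) to a nominal category; missing pairs are
    simply absent.  At least 2 coders and 2 units are required for alpha to
    be defined.
    """

    units: list[str]
    coders: list[str]
    ratings: dict[tuple[str, str], Hashable]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingsMatrix":
        """Build from a coders x units frame; NaN marks a missing rating."""
        ratings = {}
        for coder in df.index:
            for unit in df.columns:
                v = df.loc[coder, unit]
                if pd.notna(v):
                    ratings[(str(coder), str(unit))] = v
        return cls(
            units=[str(u) for u in df.columns],
            coders=[str(c) for c in df.index],
            ratings=ratings,
        )

    def values_by_unit(self) -> dict[str, list[Hashable]]:
        by_unit: dict[str, list[Hashable]] = {u: [] for u in self.units}
        for (coder, unit), v in self.ratings.items():
            by_unit.setdefault(unit, []).append(v)
        return by_unit


def krippendorff_alpha(ratings: RatingsMatrix, level: str = "nominal") -> float:
    """Krippendorff's alpha for nominal data via the coincidence matrix.

    Each unit coded by m >= 2 coders contributes its ordered value pairs with
    weight 1/(m-1) to the coincidence matrix o_ck; with value marginals
    n_c = sum_k o_ck and n = sum_c n_c,

        alpha = 1 - (n - 1) * sum_{c != k} o_ck / sum_{c != k} n_c n_k .

    Units with fewer than two ratings are ignored.  Raises when fewer than
    two units are pairable or when only one category occurs (expected
    disagreement zero).
    """
    if level != "nominal":
        raise ValueError("only nominal-level alpha is implemented")
    if len(ratings.coders) < 2:
        raise ValueError("alpha requires at least 2 coders")
    by_unit = ratings.values_by_unit()
    cats = sorted({v for vs in by_unit.values() for v in vs}, key=str)
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    o = np.zeros((k, k))
    pairable_units = 0
    for vs in by_unit.values():
        m = len(vs)
        if m < 2:
            continue
        pairable_units += 1
        w = 1.0 / (m - 1)
        for i in range(m):
            for j in range(m):
                if i != j:
                    o[idx[vs[i]], idx[vs[j]]] += w
    if pairable_units < 2:
        raise ValueError("alpha requires at least 2 units with >= 2 ratings")
    n_c = o.sum(axis=1)
    n = n_c.sum()
    off_diag = o.sum() - np.trace(o)
    expected_off = n_c.sum() ** 2 - (n_c**2).sum()
    if expected_off <= 0:
        raise ValueError("expected disagreement is zero (single category)")
    return float(1.0 - (n - 1.0) * off_diag / expected_off)


# ---------------------------------------------------------------------------
# Sampling and rounding conventions
# ---------------------------------------------------------------------------


def systematic_sample(
    ids: Sequence[str], fraction: float, rng_seed: int = 0
) -> list[str]:
    """Random systematic sample: every k-th item from a random start.

    The interval k is round(1/fraction) (at least 1); the start is uniform on
    [0, k).  The sample size is within one of n * fraction.
    """
    if not ids:
        raise ValueError("cannot sample from an empty list")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, round(1.0 / fraction))
    rng = np.random.default_rng(rng_seed)
    start = int(rng.integers(k))
    return list(ids[start::k])


def pct(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage rounded half-up (the tables' convention, not banker's)."""
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return float(value)


# ---------------------------------------------------------------------------
# End-to-end report
# ---------------------------------------------------------------------------

#: Video types tabulated against exposure, in table order.
OR_TYPES = (
    "nonvaccine",
    "vaccine",
    "provaccine",
    "antivaccine",
    "autism",
    "health",
    "health_accurate",
    "health_misinfo",
)

#: Source categories in the printed-table order.
_SOURCE_ORDER = (
    "government",
    "academic_hospital",
    "pharma_forprofit",
    "consumer",
    "news",
    "professional",
    "other",
)


@dataclass
class ReportBundle:
    """All computed tables for a collection of networks, plus the convention
    flags in effect when they were produced."""

    global_stats: dict[str, netstats.GlobalStats]
    composition: dict[str, dict]
    exposure_summary: dict[str, exposure.ExposureSummary]
    or_table: dict[str, list[dict]]
    conventions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {
            "conventions": self.conventions,
            "networks": {},
        }
        for name in self.global_stats:
            summ = self.exposure_summary[name]
            out["networks"][name] = {
                "global_stats": self.global_stats[name].to_dict(),
                "composition": self.composition[name],
                "exposure_summary": {
                    "mean": summ.mean,
                    "sd": summ.sd,
                    "n": summ.n,
                    "n_exposed": summ.n_exposed,
                    "pct_exposed": pct(summ.n_exposed, summ.n, 1),
                    "n_unexposed": summ.n - summ.n_exposed,
                    "pct_unexposed": pct(summ.n - summ.n_exposed, summ.n, 1),
                    "range_over_exposed": summ.range_over_exposed,
                },
                "odds_ratios": self.or_table[name],
            }
        return out

    def to_json(self) -> str:
        def _jsonify(obj):
            if isinstance(obj, float):
                if obj != obj:
                    return None
                if obj == float("inf"):
                    return "inf"
                if obj == float("-inf"):
                    return "-inf"
                return obj
            if isinstance(obj, dict):
                return {k: _jsonify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_jsonify(v) for v in obj]
            return obj

        return json.dumps(_jsonify(self.to_dict()), indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        """Write the bundle as JSON plus flat CSVs of both tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json(), encoding="utf-8")
        rows = []
        for name, stats in self.global_stats.items():
            row = {"network": name, **stats.to_dict()}
            comp = self.composition[name]
            for key, cell in comp.items():
                row[f"{key}_n"] = cell["n"]
                row[f"{key}_pct"] = cell["pct"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "network_table.csv", index=False)
        or_rows = []
        for name, table in self.or_table.items():
            for entry in table:
                or_rows.append({"network": name, **entry})
        pd.DataFrame(or_rows).to_csv(outdir / "odds_table.csv", index=False)


def _composition(network: RecNetwork) -> dict:
    """Category counts and percentages in the printed-table layout.

    Stance percentages are relative to vaccine-related videos, health
    accuracy percentages to health-related videos, source percentages to
    vaccine-related videos; everything else to the node count.
    """
    nodes = list(network.nodes())
    n = len(nodes)
    counts = {
        name: sum(1 for v in nodes if exposure.PREDICATES[name](v))
        for name in exposure.PREDICATES
    }
    comp: dict[str, dict] = {}

    def cell(key: str, num: int, den: int) -> None:
        comp[key] = {"n": num, "denominator": den, "pct": pct(num, den) if den else 0.0}

    cell("nonvaccine", counts["nonvaccine"], n)
    cell("vaccine", counts["vaccine"], n)
    cell("provaccine", counts["provaccine"], counts["vaccine"])
    cell("antivaccine", counts["antivaccine"], counts["vaccine"])
    cell("autism", counts["autism"], n)
    cell("health", counts["health"], n)
    cell("health_accurate", counts["health_accurate"], counts["health"])
    cell("health_misinfo", counts["health_misinfo"], counts["health"])
    vaccine_nodes = [v for v in nodes if v.vaccine_related]
    for source in _SOURCE_ORDER:
        num = sum(1 for v in vaccine_nodes if v.source.value == source)
        cell(f"source_{source}", num, len(vaccine_nodes))
    return comp


def run_report(
    networks: Mapping[str, RecNetwork],
    *,
    alpha: float = 0.05,
    ci_method: str = "exact_conditional",
    recode: bool = True,
    outdir: str | Path | None = None,
) -> ReportBundle:
    """Run every analysis stage over each network, in study order.

    Stages: stance recoding (unless ``recode`` is False), global statistics,
    category composition, per-node exposure to antivaccine videos with its
    summary, and the per-type exposed-by-type odds-ratio table.  The bundle
    is deterministic given the inputs; convention flags are recorded in its
    metadata.  With ``outdir`` set, CSV and JSON outputs are written there.
    """
    if not networks:
        raise ValueError("no networks supplied")
    global_stats = {}
    composition = {}
    summaries = {}
    or_tables = {}
    for name, net in networks.items():
        if net.n_nodes == 0:
            raise ValueError(f"network {name!r} is empty")
        if recode:
            net = net.with_nodes([recode_stance(v) for v in net.nodes()])
        global_stats[name] = netstats.compute_global_stats(net)
        composition[name] = _composition(net)
        result = exposure.network_exposure(net, "antivaccine")
        summaries[name] = exposure.exposure_summary(result)
        flags = exposure.exposed_flags(result)
        table_rows = []
        for type_name in OR_TYPES:
            table = casecontrol.build_table(net, exposure.PREDICATES[type_name], flags)
            entry: dict = {
                "type": type_name,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
            }
            try:
                point = casecontrol.odds_ratio(table)
            except ValueError:
                entry.update(odds_ratio=None, ci_low=None, ci_high=None, method=None)
                table_rows.append(entry)
                continue
            try:
                if ci_method == "woolf":
                    res = casecontrol.woolf_ci(table, alpha)
                elif ci_method == "cornfield_approx":
                    res = casecontrol.cornfield_approx_ci(table, alpha)
                else:
                    res = casecontrol.exact_ci(table, alpha)
                entry.update(
                    odds_ratio=point,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    method=res.method,
                )
            except ValueError as exc:
                logger.warning("CI unavailable for type %s: %s", type_name, exc)
                entry.update(odds_ratio=point, ci_low=None, ci_high=None, method=None)
            table_rows.append(entry)
        or_tables[name] = table_rows
    bundle = ReportBundle(
        global_stats=global_stats,
        composition=composition,
        exposure_summary=summaries,
        or_table=or_tables,
        conventions={
            "exposure_attribute": "antivaccine (stance=anti after recoding)",
            "recode_applied": recode,
            "ci_method": ci_method,
            "alpha": alpha,
            "clustering_low_degree_counted": True,
            "diameter_convention": "largest connected component",
            "rounding": "half-up",
            "sd": "sample (n-1)",
        },
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
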