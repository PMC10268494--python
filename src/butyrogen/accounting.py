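"""Carbon-share and yield accounting for culture endpoint measurements.

Monocultures of acetate-consuming butyrogens defeat ordinary carbon-recovery
accounting: the CoA transferase consumes one free acetate per butyrate
released, so measured net acetate can be negative even while acetate kinase
still runs.  The monoculture metric therefore credits one mole of
"theoretically consumed" acetate per mole of butyrate produced, counts total
fermented carbon as

    C_total = 6 * glucose_consumed + 2 * butyrate_produced

and expresses each product as the percent of that carbon pool it captured,
with acetate's share computed from total acetate produced
(= butyrate_produced + measured net change).

For multi-species communities the simpler Delta-product per mole of substrate
consumed is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: carbon atoms per molecule for the accounted products
CARBON_ATOMS = {"acetate": 2, "butyrate": 4, "lactate": 3, "formate": 1,
                "propionate": 3, "succinate": 4}

#: products assumed absent from the medium and not consumed
PRODUCED_ONLY = ("butyrate", "lactate", "formate")


class UndefinedMetricError(ValueError):
    """No substrate was consumed, so per-substrate metrics are undefined."""


@dataclass
class CultureRecord:
    """Endpoint and blank-medium concentrations (mmol/L) for one culture."""

    culture_id: str
    strain: str
    condition: str
    endpoint: dict[str, float]
    blank: dict[str, float]
    headspace: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for which, conc in (("endpoint", self.endpoint), ("blank", self.blank)):
            for analyte, v in conc.items():
                if v < 0:
                    raise ValueError(f"{self.culture_id}: negative {which} {analyte} ({v})")

    def consumed(self, analyte: str) -> float:
        """Blank minus endpoint; negative consumption raises for substrates."""
        return self.blank.get(analyte, 0.0) - self.endpoint.get(analyte, 0.0)

    def delta(self, analyte: str) -> float:
        """Endpoint minus blank (net production, may be negative)."""
        return self.endpoint.get(analyte, 0.0) - self.blank.get(analyte, 0.0)

    def produced(self, analyte: str) -> float:
        """Net production clipped at zero for medium-absent products."""
        d = self.delta(analyte)
        if analyte in PRODUCED_ONLY and d < 0:
            warnings.warn(
                f"{self.culture_id}: measured {analyte} below blank ({d:.3g} mM); "
                "clipping to 0 (not expected in the medium nor consumed)",
                stacklevel=2,
            )
            return 0.0
        return d

    def substrate_consumed(self) -> float:
        """Total hexose consumed (glucose + fructose when present), mM."""
        total = 0.0
        for sugar in ("glucose", "fructose"):
            if sugar in self.blank or sugar in self.endpoint:
                c = self.consumed(sugar)
                if c < 0:
                    raise ValueError(
                        f"{self.culture_id}: negative {sugar} consumption ({c:.3g} mM)"
                    )
                total += c
        return total


@dataclass
class CarbonShares:
    """Percent-of-total-fermented-carbon result for a monoculture."""

    shares_percent: dict[str, float]
    theoretical_acetate_consumed_mM: float
    total_fermented_carbon_mM: float
    total_acetate_produced_mM: float
    flagged: bool = False  # True when total acetate produced went negative

    def to_series(self) -> pd.Series:
        return pd.Series(self.shares_percent, name="percent_total_fermented_carbon")


def monoculture_shares(rec: CultureRecord) -> CarbonShares:
    """Percent of total fermented carbon captured by each product.

    Theoretical acetate consumed equals butyrate produced (one acetate per
    CoA-transferase turnover); total fermented carbon is consumed-hexose
    carbon plus that acetate carbon.  Acetate's share uses total acetate
    produced; butyrate, lactate and formate use their endpoint production.
    A negative total acetate produced violates the accounting assumption and
    flags the result rather than being clipped.
    """
    sugars = rec.substrate_consumed()
    if sugars <= 0:
        raise UndefinedMetricError(
            f"{rec.culture_id}: no substrate consumed; carbon shares undefined"
        )
    butyrate = rec.produced("butyrate")
    theo_acetate = butyrate
    total_c = 6.0 * sugars + 2.0 * theo_acetate
    total_acetate = theo_acetate + rec.delta("acetate")
    flagged = total_acetate < 0

    produced = {
        "acetate": total_acetate,
        "butyrate": butyrate,
        "lactate": rec.produced("lactate"),
        "formate": rec.produced("formate"),
    }
    shares = {
        p: 100.0 * CARBON_ATOMS[p] * amount / total_c for p, amount in produced.items()
    }
    return CarbonShares(
        shares_percent=shares,
        theoretical_acetate_consumed_mM=theo_acetate,
        total_fermented_carbon_mM=total_c,
        total_acetate_produced_mM=total_acetate,
        flagged=flagged,
    )


def community_yields(rec: CultureRecord,
                     products: Sequence[str] = ("acetate", "butyrate", "lactate",
                                                "formate", "propionate", "succinate")
                     ) -> dict[str, float]:
    """Net change of each product per mole of substrate consumed (mol/mol).

    Acetate may legitimately be negative (net community consumption).
    """
    sugars = rec.substrate_consumed()
    if sugars <= 0:
        raise UndefinedMetricError(
            f"{rec.culture_id}: no substrate consumed; community yields undefined"
        )
    out = {}
    for p in products:
        if p in rec.endpoint or p in rec.blank:
            out[p] = rec.delta(p) / sugars
    return out


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Student's two-sample t-test (pooled variance).

    Two identical constant groups are reported as t = 0, p = 1 rather than
    the 0/0 indeterminate form.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates for a t-test")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ContrastResults:
    """Per-product group comparison between two culture conditions."""

    group_a: str
    group_b: str
    table: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Condition contrast: {self.group_a} vs {self.group_b}", ""]
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def condition_contrast(records: Iterable[CultureRecord], group_a: str, group_b: str,
                       metric: str | Callable[[CultureRecord], Mapping[str, float]]
                       = "community_yields") -> ContrastResults:
    """Compare a per-product metric between two condition groups.

    ``metric`` is ``"community_yields"``, ``"monoculture_shares"`` or any
    callable mapping a record to per-product values.  Each product gets
    group means, SEM, the two-sided two-sample t statistic, p-value and the
    figure-legend star coding (* <0.05, ** <0.01, *** <0.001).
    """
    if metric == "community_yields":
        fn = community_yields
    elif metric == "monoculture_shares":
        fn = lambda r: monoculture_shares(r).shares_percent  # noqa: E731
    elif callable(metric):
        fn = metric
    else:
        raise ValueError(f"unknown metric {metric!r}")

    values: dict[str, dict[str, list[float]]] = {}
    counts = {group_a: 0, group_b: 0}
    for rec in records:
        if rec.condition not in (group_a, group_b):
            continue
        counts[rec.condition] += 1
        for product, v in fn(rec).items():
            values.setdefault(product, {group_a: [], group_b: []})[rec.condition].append(v)
    for g, n in counts.items():
        if n < 2:
            raise ValueError(f"group {g!r} has {n} replicate(s); need >= 2")

    rows = []
    for product, groups in values.items():
        a, b = np.asarray(groups[group_a]), np.asarray(groups[group_b])
        t, p = two_sample_t(a, b)
        rows.append({
            "product": product,
            f"mean_{group_a}": a.mean(),
            f"sem_{group_a}": a.std(ddof=1) / np.sqrt(len(a)),
            f"mean_{group_b}": b.mean(),
            f"sem_{group_b}": b.std(ddof=1) / np.sqrt(len(b)),
            "t": t,
            "p": p,
            "stars": significance_stars(p),
        })
    return ContrastResults(group_a=group_a, group_b=group_b, table=pd.DataFrame(rows))
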