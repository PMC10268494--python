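"""Synthetic culture and cohort data with the structure the analyses assume.

Culture generator
-----------------
Each `StrainProfile` carries baseline product yields (mol per mol glucose)
and multiplicative shifts applied under H2-rich (or CO, hydrogenase-
inhibited) conditions.  Before noise is added, every yield vector is closed
into a full elemental balance via the stoichiometry module, so generated
data always respect conservation; hydrogenase-free profiles must close with
zero H2 and carry no H2 response at all.  Measurement noise is mean-one
multiplicative log-normal on the concentration changes (HPLC error is
roughly proportional and concentrations are positive); additive Gaussian is
available as an alternative.

Cohort generator
----------------
Subjects carry persistent methanogenic status and subject-level random
effects; breath and fecal samples add within-subject noise.  The programmed
methanogen deficits in breath H2 and fecal butyrate are applied *only* in
the during-supplement period, so the before period is an exact null for the
MG vs non-MG comparison.  Injected outliers are tagged in hidden ``_truth``
columns that the analysis readers ignore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accounting import CultureRecord
from .stoichiometry import balance_check, close_balance

PRODUCTS = ("acetate", "butyrate", "lactate", "formate")

#: default blank (uninoculated) medium, mM: glucose-supplemented, acetate-rich
DEFAULT_BLANK_MM = {"glucose": 22.2, "acetate": 30.0, "butyrate": 0.0,
                    "lactate": 0.0, "formate": 0.0}


@dataclass(frozen=True)
class StrainProfile:
    """Fermentation phenotype of one strain for the culture generator.

    ``h2_effects`` are multiplicative factors applied to the yields under
    H2/CO conditions (1.0 = no response).  A hydrogenase-free strain cannot
    sense H2: its effects must all be 1.0 and its yield vector must close
    with zero H2 production.
    """

    name: str
    has_hydrogenase: bool
    yields: Mapping[str, float]
    h2_effects: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for p, y in self.yields.items():
            if y < 0:
                raise ValueError(f"{self.name}: negative yield for {p}")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: negative noise_sd")
        if not self.has_hydrogenase:
            off = {p: f for p, f in self.h2_effects.items() if f != 1.0}
            if off:
                raise ValueError(
                    f"{self.name}: hydrogenase-free profile cannot respond to H2 "
                    f"(non-neutral effects {off})"
                )
        # conservation must be satisfiable in both conditions
        for shifted in (False, True):
            bal = close_balance(self.effective_yields(shifted))
            if not balance_check(bal).ok:  # pragma: no cover - closure guarantees this
                raise ValueError(f"{self.name}: yields do not close to a balance")
            if not self.has_hydrogenase and abs(bal.coefficient("H2")) > 1e-9:
                raise ValueError(
                    f"{self.name}: hydrogenase-free profile closes with "
                    f"{bal.coefficient('H2'):.3g} H2 per glucose; electron balance "
                    "requires zero"
                )

    def effective_yields(self, shifted: bool) -> dict[str, float]:
        out = {p: float(self.yields.get(p, 0.0)) for p in PRODUCTS}
        if shifted:
            for p in PRODUCTS:
                out[p] *= float(self.h2_effects.get(p, 1.0))
        return out


def default_profiles() -> list[StrainProfile]:
    """Three illustrative strain phenotypes.

    One diverts reductant to butyrate and formate under H2, one mostly to
    lactate, and the hydrogenase-free one does not respond at all — the
    qualitative response patterns of the three major gut butyrogen types.
    Effect sizes are illustrative defaults, not measured values.
    """
    return [
        StrainProfile(
            name="butyrate_responder", has_hydrogenase=True,
            yields={"butyrate": 0.8, "acetate": 0.3, "lactate": 0.005, "formate": 0.1},
            h2_effects={"butyrate": 1.3, "acetate": 0.6, "lactate": 3.0, "formate": 2.5},
        ),
        StrainProfile(
            name="lactate_responder", has_hydrogenase=True,
            yields={"butyrate": 0.7, "acetate": 0.5, "lactate": 0.05, "formate": 0.15},
            h2_effects={"butyrate": 1.0, "acetate": 0.5, "lactate": 8.0, "formate": 2.0},
        ),
        StrainProfile(
            name="nonresponder", has_hydrogenase=False,
            yields={"butyrate": 1.0, "acetate": 0.25, "lactate": 0.1, "formate": 0.4},
        ),
    ]


def _noise_factors(rng: np.random.Generator, rel_sd: float, n: int,
                   model: str) -> np.ndarray:
    if rel_sd == 0:
        return np.ones(n)
    if model == "lognormal":
        sigma = np.sqrt(np.log1p(rel_sd ** 2))
        return rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=n)
    if model == "additive":
        return 1.0 + rng.normal(0.0, rel_sd, size=n)
    raise ValueError(f"unknown noise model {model!r}")


def gen_cultures(profiles: Sequence[StrainProfile] | None = None,
                 conditions: Sequence[str] = ("N2", "H2"),
                 replicates: int = 4, seed: int | None = None,
                 glucose_consumed_mM: float = 20.0,
                 blank_mM: Mapping[str, float] | None = None,
                 shifted_conditions: Iterable[str] = ("H2", "CO"),
                 noise_model: str = "lognormal") -> list[CultureRecord]:
    """Generate endpoint culture records for each profile x condition.

    Per replicate, product changes are ``yield * glucose_consumed`` with
    multiplicative noise applied to the changes (never to the blank), and
    the headspace H2 reading comes from the closed balance's H2 coefficient.
    A fixed seed regenerates the dataset bit-identically.
    """
    if replicates < 2:
        raise ValueError("need replicates >= 2")
    profiles = list(profiles) if profiles is not None else default_profiles()
    blank = dict(DEFAULT_BLANK_MM)
    if blank_mM:
        blank.update(blank_mM)
    shifted_conditions = set(shifted_conditions)
    rng = np.random.default_rng(seed)

    records: list[CultureRecord] = []
    for prof in profiles:
        for cond in conditions:
            shifted = cond in shifted_conditions
            yields = prof.effective_yields(shifted)
            balance = close_balance(yields)  # conservation checked pre-noise
            for i in range(replicates):
                factors = _noise_factors(rng, prof.noise_sd, len(PRODUCTS) + 1,
                                         noise_model)
                consumed = glucose_consumed_mM * factors[0]
                endpoint = {"glucose": max(blank["glucose"] - consumed, 0.0)}
                for j, p in enumerate(PRODUCTS):
                    delta = yields[p] * consumed * factors[j + 1]
                    endpoint[p] = max(blank.get(p, 0.0) + delta, 0.0)
                records.append(CultureRecord(
                    culture_id=f"{prof.name}-{cond}-r{i + 1}",
                    strain=prof.name, condition=cond,
                    endpoint=endpoint, blank=dict(blank),
                    headspace={"H2": balance.coefficient("H2") * consumed},
                ))
    return records


def cultures_to_frame(records: Sequence[CultureRecord]) -> pd.DataFrame:
    """Flatten culture records into the delimited-text schema."""
    rows = []
    for r in records:
        row = {"culture_id": r.culture_id, "strain": r.strain, "condition": r.condition}
        for analyte, v in r.endpoint.items():
            row[f"endpoint_{analyte}_mM"] = v
        for analyte, v in r.blank.items():
            row[f"blank_{analyte}_mM"] = v
        for gas, v in r.headspace.items():
            row[f"headspace_{gas}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def cultures_from_frame(frame: pd.DataFrame) -> list[CultureRecord]:
    records = []
    for _, row in frame.iterrows():
        endpoint, blank, headspace = {}, {}, {}
        for col, v in row.items():
            if col.startswith("endpoint_"):
                endpoint[col[len("endpoint_"):-len("_mM")]] = float(v)
            elif col.startswith("blank_"):
                blank[col[len("blank_"):-len("_mM")]] = float(v)
            elif col.startswith("headspace_"):
                headspace[col[len("headspace_"):]] = float(v)
        records.append(CultureRecord(
            culture_id=str(row["culture_id"]), strain=str(row["strain"]),
            condition=str(row["condition"]), endpoint=endpoint, blank=blank,
            headspace=headspace,
        ))
    return records


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic supplement cohort.

    Breath H2 in ppm (CO2-normalized scale), fecal butyrate in umol per g
    wet weight.  ``*_between_sd`` are subject-level random effects,
    ``*_within_sd`` sample-level noise.  The supplement raises H2 and
    butyrate in everyone (``*_during_increase``); the methanogen deficits
    (``mg_during_*_deficit``) act only during supplementation.
    """

    n_subjects: int = 40
    frac_methanogenic: float = 0.5
    n_samples_per_period: int = 3
    h2_mean: float = 12.0
    h2_between_sd: float = 3.0
    h2_within_sd: float = 2.0
    h2_during_increase: float = 6.0
    ch4_mg_mean: float = 15.0
    ch4_mg_sd: float = 5.0
    ch4_nonmg_mean: float = 0.5
    ch4_nonmg_sd: float = 0.3
    butyrate_mean: float = 10.0
    butyrate_between_sd: float = 2.5
    butyrate_within_sd: float = 1.5
    butyrate_during_increase: float = 3.0
    mg_during_h2_deficit: float = 6.0
    mg_during_butyrate_deficit: float = 5.0
    ch4_threshold_ppm: float = 4.0
    co2_mean_pct: float = 3.5
    co2_sd_pct: float = 0.8
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 10.0
    semester: str = "S1"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("need n_subjects >= 4")
        if not 0.0 <= self.frac_methanogenic <= 1.0:
            raise ValueError("frac_methanogenic must be in [0, 1]")
        for name in ("h2_between_sd", "h2_within_sd", "ch4_mg_sd", "ch4_nonmg_sd",
                     "butyrate_between_sd", "butyrate_within_sd", "co2_sd_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (breath, fecal) sample tables for a synthetic cohort.

    Methanogenic subjects are guaranteed at least one breath CH4 draw over
    the classification threshold in each period; non-methanogenic CH4 is
    capped at the threshold so ``frac_methanogenic=0`` cohorts classify
    entirely non-MG.  Ground truth (status, injected outliers) is stored in
    ``_truth_*`` columns.
    """
    rng = np.random.default_rng(params.seed)
    n_mg = int(round(params.n_subjects * params.frac_methanogenic))
    is_mg = np.zeros(params.n_subjects, bool)
    is_mg[:n_mg] = True
    rng.shuffle(is_mg)

    breath_rows, fecal_rows = [], []
    for s in range(params.n_subjects):
        subject = f"S{s + 1:03d}"
        mg = bool(is_mg[s])
        h2_base = max(rng.normal(params.h2_mean, params.h2_between_sd), 0.5)
        but_base = max(rng.normal(params.butyrate_mean, params.butyrate_between_sd), 0.5)
        for period in ("before", "during"):
            during = period == "during"
            h2_level = h2_base + (params.h2_during_increase if during else 0.0)
            but_level = but_base + (params.butyrate_during_increase if during else 0.0)
            if mg and during:
                h2_level -= params.mg_during_h2_deficit
                but_level -= params.mg_during_butyrate_deficit

            if mg:
                ch4 = np.clip(rng.normal(params.ch4_mg_mean, params.ch4_mg_sd,
                                         params.n_samples_per_period), 0.0, None)
                if ch4.max() <= params.ch4_threshold_ppm:
                    ch4[np.argmax(ch4)] = params.ch4_threshold_ppm + 1.0 + \
                        abs(rng.normal(0.0, 1.0))
            else:
                ch4 = np.clip(rng.normal(params.ch4_nonmg_mean, params.ch4_nonmg_sd,
                                         params.n_samples_per_period),
                              0.0, params.ch4_threshold_ppm)

            h2_total_sd = float(np.hypot(params.h2_between_sd, params.h2_within_sd))
            but_total_sd = float(np.hypot(params.butyrate_between_sd,
                                          params.butyrate_within_sd))
            for i in range(params.n_samples_per_period):
                h2 = max(rng.normal(h2_level, params.h2_within_sd), 0.0)
                outlier = rng.random() < params.outlier_rate
                if outlier:
                    h2 += params.outlier_magnitude_sd * h2_total_sd
                co2 = float(np.clip(rng.normal(params.co2_mean_pct, params.co2_sd_pct),
                                    1.5, 6.0))
                scale = co2 / 3.5  # raw readings de-normalized by sample CO2
                breath_rows.append({
                    "subject": subject, "semester": params.semester, "period": period,
                    "h2_ppm": h2 * scale, "ch4_ppm": ch4[i] * scale, "co2_pct": co2,
                    "_truth_mg": mg, "_truth_outlier": outlier,
                })
                but = max(rng.normal(but_level, params.butyrate_within_sd), 0.0)
                f_outlier = rng.random() < params.outlier_rate
                if f_outlier:
                    but += params.outlier_magnitude_sd * but_total_sd
                fecal_rows.append({
                    "subject": subject, "period": period, "analyte": "butyrate",
                    "value": but, "_truth_mg": mg, "_truth_outlier": f_outlier,
                })
    return pd.DataFrame(breath_rows), pd.DataFrame(fecal_rows)
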