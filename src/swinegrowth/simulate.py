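"""Synthetic two-breed herd generator.

Emulates the data structure the analysis pipeline expects, with known
ground truth, so every stage is testable without animal records:

* longitudinal body weights: per-animal logistic curves whose asymptote A
  varies between animals (multiplicative Gaussian, CV-parameterized) with
  multiplicative Gaussian measurement noise on each weighing;
* a slaughter trait table: animals drawn into 10-kg weight bins with
  configured per-group sizes and mean body weights, each trait following a
  programmed response to body weight (linear up/down, flat, or saturating
  asymptotic) plus additive Gaussian noise — with the programmed trend
  directions emitted as a truth table;
* a tidy qPCR Ct table: reference-gene Ct ~ N(20, 0.2^2) per sample, target
  Ct = reference + gene-specific dCt + programmed ddCt per group + noise.

The default spec encodes a lean breed ("YP": fast growth, muscle area
saturating ~130 kg) and a fat breed ("QYP": slow growth, intramuscular fat
saturating ~110 kg) with 10 up / 2 down programmed trait trends for the
lean configuration and 15 up / 5 down for the fat one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .growth import LogisticParams

__all__ = [
    "TraitResponse",
    "BreedGrowthSpec",
    "SlaughterDesign",
    "QpcrSpec",
    "BreedSpec",
    "SyntheticHerdSpec",
    "default_herd_spec",
    "simulate_herd",
    "simulate_slaughter",
    "simulate_qpcr",
    "with_noise_free",
]

# saturation rate giving a slope-threshold (10%) plateau 50 kg past range start
_PLATEAU_C = math.log(10.0) / 50.0


@dataclass(frozen=True)
class TraitResponse:
    """Programmed mean response of one trait to body weight.

    kind:
      * "linear": mean = baseline + slope * (bw - bw_ref)
      * "flat":   mean = baseline
      * "asymptotic": mean = a - b * exp(-c * bw) (slope, baseline unused)

    ``sd`` is the additive within-group noise SD in trait units.
    """

    kind: str
    baseline: float = 0.0
    slope: float = 0.0
    asym: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sd: float = 1.0

    @property
    def direction(self) -> str:
        """Programmed trend direction over increasing body weight."""
        if self.kind == "flat":
            return "unchanged"
        if self.kind == "asymptotic":
            return "up" if self.asym[1] * self.asym[2] > 0 else "down"
        return "up" if self.slope > 0 else ("down" if self.slope < 0 else "unchanged")

    def mean_at(self, bw, bw_ref: float):
        bw = np.asarray(bw, dtype=float)
        if self.kind == "flat":
            return np.full_like(bw, self.baseline)
        if self.kind == "asymptotic":
            a, b, c = self.asym
            return a - b * np.exp(-c * bw)
        return self.baseline + self.slope * (bw - bw_ref)


@dataclass(frozen=True)
class BreedGrowthSpec:
    """Longitudinal weighing design for one breed."""

    params: LogisticParams
    n_animals: int
    cv_asymptote: float = 0.05
    cv_measurement: float = 0.02
    age_start: float = 50.0
    age_stop: float = 300.0
    age_step: float = 10.0


@dataclass(frozen=True)
class SlaughterDesign:
    """Weight-bin design of the slaughter experiment (10-kg groups)."""

    start_kg: float
    width_kg: float = 10.0
    group_n: tuple[int, ...] = ()
    group_mean_bw: tuple[float, ...] = ()
    group_sd_bw: tuple[float, ...] = ()

    @property
    def n_groups(self) -> int:
        return len(self.group_n)


@dataclass(frozen=True)
class QpcrSpec:
    """qPCR design: genes x (breed-stage) groups with programmed ddCt."""

    genes: tuple[str, ...]
    stages: int = 4
    n_per_group: int = 6
    # per-gene ddCt increment per stage step (stage 1 is the calibrator)
    ddct_per_stage: dict = field(default_factory=dict)
    baseline_dct: float = 4.0
    noise_sd: float = 0.15
    ref_ct_mean: float = 20.0
    ref_ct_sd: float = 0.2


@dataclass(frozen=True)
class BreedSpec:
    """Everything simulated for one breed."""

    name: str
    growth: BreedGrowthSpec
    slaughter: SlaughterDesign
    traits: dict  # trait name -> TraitResponse
    qpcr: QpcrSpec


@dataclass(frozen=True)
class SyntheticHerdSpec:
    """Full parameterization of the synthetic herd (plus the master seed)."""

    breeds: tuple[BreedSpec, ...]
    seed: int = 17

    def breed(self, name: str) -> BreedSpec:
        for b in self.breeds:
            if b.name == name:
                return b
        raise KeyError(name)


def _lean_traits() -> dict:
    """Lean-breed trait responses: 10 up, 2 down, 16 flat (28 traits).

    Programmed directional effects are >= 1.5 within-group SD per 10 kg.
    LMA saturates (asymptotic, plateau ~ range start + 50 kg); IMF rises
    linearly — the lean-type pattern.
    """
    up = {
        "CW": TraitResponse("linear", 60.0, 0.74, sd=2.0),
        "DP": TraitResponse("linear", 70.0, 0.15, sd=0.8),
        "backfat1": TraitResponse("linear", 18.0, 0.35, sd=2.0),
        "backfat2": TraitResponse("linear", 22.0, 0.35, sd=2.0),
        "backfat3": TraitResponse("linear", 20.0, 0.35, sd=2.0),
        "backfat4": TraitResponse("linear", 15.0, 0.35, sd=2.0),
        "LMA": TraitResponse("asymptotic", asym=(85.0, 1600.0, _PLATEAU_C), sd=3.0),
        "IMF": TraitResponse("linear", 1.8, 0.045, sd=0.25),
        "marbling": TraitResponse("linear", 1.5, 0.04, sd=0.25),
        "SF": TraitResponse("linear", 40.0, 0.6, sd=3.5),
    }
    down = {
        "MC": TraitResponse("linear", 75.0, -0.08, sd=0.5),
        "DL": TraitResponse("linear", 4.5, -0.04, sd=0.25),
    }
    flat = {
        "CL1": TraitResponse("flat", 95.0, sd=3.0),
        "CL2": TraitResponse("flat", 78.0, sd=3.0),
        "LF": TraitResponse("flat", 2.5, sd=0.4),
        "LP": TraitResponse("flat", 60.0, sd=2.0),
        "pH1": TraitResponse("flat", 6.4, sd=0.15),
        "pH2": TraitResponse("flat", 5.6, sd=0.12),
        "L1": TraitResponse("flat", 45.0, sd=2.0),
        "a1": TraitResponse("flat", 7.0, sd=1.0),
        "b1": TraitResponse("flat", 6.0, sd=1.0),
        "L2": TraitResponse("flat", 48.0, sd=2.0),
        "a2": TraitResponse("flat", 8.0, sd=1.0),
        "b2": TraitResponse("flat", 7.0, sd=1.0),
        "CL_star": TraitResponse("flat", 30.0, sd=2.0),
        "WBC": TraitResponse("flat", 55.0, sd=3.0),
        "CP": TraitResponse("flat", 22.0, sd=1.0),
        "Ash": TraitResponse("flat", 1.1, sd=0.08),
    }
    return {**up, **down, **flat}


def _fat_traits() -> dict:
    """Fat-breed trait responses: 15 up, 5 down, 8 flat (28 traits).

    IMF saturates (plateau ~ range start + 50 kg); LMA keeps rising
    linearly — the fat-type pattern.
    """
    up = {
        "CW": TraitResponse("linear", 41.0, 0.70, sd=2.0),
        "DP": TraitResponse("linear", 68.0, 0.15, sd=0.8),
        "backfat1": TraitResponse("linear", 25.0, 0.45, sd=2.2),
        "backfat2": TraitResponse("linear", 30.0, 0.45, sd=2.2),
        "backfat3": TraitResponse("linear", 28.0, 0.45, sd=2.2),
        "backfat4": TraitResponse("linear", 22.0, 0.45, sd=2.2),
        "LMA": TraitResponse("linear", 22.0, 0.35, sd=2.0),
        "IMF": TraitResponse("asymptotic", asym=(7.0, 71.3, _PLATEAU_C), sd=0.3),
        "marbling": TraitResponse("linear", 3.0, 0.06, sd=0.3),
        "LF": TraitResponse("linear", 1.5, 0.08, sd=0.45),
        "CL1": TraitResponse("linear", 78.0, 0.8, sd=3.2),
        "CL2": TraitResponse("linear", 64.0, 0.7, sd=3.0),
        "SF": TraitResponse("linear", 35.0, 0.6, sd=3.5),
        "CP": TraitResponse("linear", 20.0, 0.2, sd=1.0),
        "Ash": TraitResponse("linear", 1.0, 0.02, sd=0.1),
    }
    down = {
        "MC": TraitResponse("linear", 75.0, -0.1, sd=0.5),
        "DL": TraitResponse("linear", 4.5, -0.04, sd=0.25),
        "pH1": TraitResponse("linear", 6.45, -0.015, sd=0.09),
        "WBC": TraitResponse("linear", 60.0, -0.5, sd=3.0),
        "LP": TraitResponse("linear", 55.0, -0.35, sd=2.0),
    }
    flat = {
        "pH2": TraitResponse("flat", 5.7, sd=0.12),
        "L1": TraitResponse("flat", 43.0, sd=2.0),
        "a1": TraitResponse("flat", 9.0, sd=1.0),
        "b1": TraitResponse("flat", 6.5, sd=1.0),
        "L2": TraitResponse("flat", 46.0, sd=2.0),
        "a2": TraitResponse("flat", 10.0, sd=1.0),
        "b2": TraitResponse("flat", 7.5, sd=1.0),
        "CL_star": TraitResponse("flat", 32.0, sd=2.0),
    }
    return {**up, **down, **flat}


_MYOGENIC = ("MyoD", "MyoG", "Mb")
_MYOSTATIN = ("MSTN",)
_ADIPOGENIC = ("PPARG", "FABP4", "LEP", "SCD")


def _qpcr_spec(lean: bool) -> QpcrSpec:
    """Programmed ddCt trends: myogenic folds fall with weight in the lean
    configuration and rise in the fat one; MSTN and adipogenic genes move
    oppositely."""
    sign = 1.0 if lean else -1.0
    per_stage = {}
    for g in _MYOGENIC:
        per_stage[g] = 0.8 * sign  # ddCt up => fold down
    for g in _MYOSTATIN:
        per_stage[g] = -0.8 * sign
    for g in _ADIPOGENIC:
        per_stage[g] = -0.6 * sign
    return QpcrSpec(
        genes=_MYOGENIC + _MYOSTATIN + _ADIPOGENIC,
        stages=4,
        n_per_group=6,
        ddct_per_stage=per_stage,
    )


def default_herd_spec(seed: int = 17) -> SyntheticHerdSpec:
    """The default two-breed study design.

    Growth truth uses the published population parameters for a Yorkshire-
    like lean breed (A=160.493 kg, B=16.901, K=0.022/d; n=400) and a
    Qingyu-like fat breed (A=137.948 kg, B=20.059, K=0.016/d; n=126), with
    5% between-animal asymptote CV and 2% measurement CV.  The slaughter
    design mirrors the published 8 x 10-kg group layout (group sizes, mean
    body weights and SDs), starting at 80 kg for the lean breed and 60 kg
    for the fat breed.
    """
    yp = BreedSpec(
        name="YP",
        growth=BreedGrowthSpec(
            params=LogisticParams(160.493, 16.901, 0.022),
            n_animals=400,
            age_stop=300.0,
        ),
        slaughter=SlaughterDesign(
            start_kg=80.0,
            group_n=(8, 22, 37, 40, 20, 26, 17, 14),
            group_mean_bw=(84.93, 95.46, 104.80, 114.72, 123.37, 134.25, 142.88, 153.79),
            group_sd_bw=(2.80, 3.05, 2.72, 3.10, 2.83, 2.76, 3.10, 2.81),
        ),
        traits=_lean_traits(),
        qpcr=_qpcr_spec(lean=True),
    )
    qyp = BreedSpec(
        name="QYP",
        growth=BreedGrowthSpec(
            params=LogisticParams(137.948, 20.059, 0.016),
            n_animals=126,
            age_stop=400.0,
        ),
        slaughter=SlaughterDesign(
            start_kg=60.0,
            group_n=(7, 6, 6, 17, 11, 6, 12, 8),
            group_mean_bw=(64.85, 77.48, 85.87, 94.07, 105.89, 113.52, 123.88, 135.53),
            group_sd_bw=(3.70, 2.02, 2.60, 3.11, 3.33, 2.11, 3.12, 4.67),
        ),
        traits=_fat_traits(),
        qpcr=_qpcr_spec(lean=False),
    )
    return SyntheticHerdSpec(breeds=(yp, qyp), seed=seed)


def _rng(spec_seed: int, seed: int | None, stream: int) -> np.random.Generator:
    base = spec_seed if seed is None else seed
    return np.random.default_rng([stream, base])


def simulate_herd(spec: SyntheticHerdSpec, seed: int | None = None) -> pd.DataFrame:
    """Longitudinal weights for all breeds.

    Per animal i: A_i = A*(1 + eps_i), eps_i ~ N(0, CV_A^2); observed weight
    at age t is logistic(A_i, B, K, t)*(1 + eta), eta ~ N(0, CV_obs^2).
    Returns columns animal_id, breed, age_days, weight_kg; deterministic
    given the spec and seed.
    """
    rng = _rng(spec.seed, seed, stream=1)
    frames = []
    for breed in spec.breeds:
        g = breed.growth
        p = g.params
        ages = np.arange(g.age_start, g.age_stop + g.age_step / 2, g.age_step)
        a_i = p.A * (1.0 + g.cv_asymptote * rng.standard_normal(g.n_animals))
        a_i = np.clip(a_i, 0.2 * p.A, None)
        curve = 1.0 / (1.0 + p.B * np.exp(-p.K * ages))  # shared shape
        w = a_i[:, None] * curve[None, :]
        if g.cv_measurement > 0:
            w = w * (1.0 + g.cv_measurement * rng.standard_normal(w.shape))
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": np.repeat(
                        [f"{breed.name}_{i + 1:04d}" for i in range(g.n_animals)],
                        len(ages),
                    ),
                    "breed": breed.name,
                    "age_days": np.tile(ages, g.n_animals),
                    "weight_kg": w.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_slaughter(
    spec: SyntheticHerdSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slaughter trait table plus the programmed-truth table.

    Body weights are drawn per group from a normal truncated to the group's
    10-kg bin (so group membership is exact by construction); each trait is
    its programmed mean response at that body weight plus additive Gaussian
    noise.  Returns (trait_table, truth) where truth has one row per
    breed x trait with the programmed direction and response kind.
    """
    rng = _rng(spec.seed, seed, stream=2)
    rows, truth_rows = [], []
    for breed in spec.breeds:
        d = breed.slaughter
        bws = []
        for gi in range(d.n_groups):
            lo = d.start_kg + gi * d.width_kg
            hi = lo + d.width_kg
            mu, sd = d.group_mean_bw[gi], d.group_sd_bw[gi]
            a, b = (lo - mu) / sd, (hi - 1e-9 - mu) / sd
            bws.append(
                stats.truncnorm.rvs(
                    a, b, loc=mu, scale=sd, size=d.group_n[gi], random_state=rng
                )
            )
        bw = np.concatenate(bws)
        table = pd.DataFrame(
            {
                "animal_id": [
                    f"{breed.name}_S{i + 1:03d}" for i in range(len(bw))
                ],
                "breed": breed.name,
                "bw": bw,
            }
        )
        for trait, resp in breed.traits.items():
            mean = resp.mean_at(bw, bw_ref=d.start_kg)
            noise = resp.sd * rng.standard_normal(len(bw)) if resp.sd > 0 else 0.0
            table[trait] = mean + noise
            truth_rows.append(
                {
                    "breed": breed.name,
                    "trait": trait,
                    "direction": resp.direction,
                    "kind": resp.kind,
                    "sd": resp.sd,
                }
            )
        rows.append(table)
    return pd.concat(rows, ignore_index=True), pd.DataFrame(truth_rows)


def simulate_qpcr(
    spec: SyntheticHerdSpec, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy Ct table plus programmed-ddCt truth.

    Groups are labelled ``<breed>_S<stage>`` with stage 1 the calibrator of
    its breed.  Every sample carries the reference gene GAPDH
    (Ct ~ N(ref_ct_mean, ref_ct_sd^2)) and each target gene at
    Ct = reference + baseline_dct + programmed ddCt + N(0, noise_sd^2).
    """
    rng = _rng(spec.seed, seed, stream=3)
    ct_rows, truth_rows = [], []
    for breed in spec.breeds:
        q = breed.qpcr
        for stage in range(1, q.stages + 1):
            group = f"{breed.name}_S{stage}"
            for s in range(q.n_per_group):
                sample = f"{group}_r{s + 1}"
                ref_ct = q.ref_ct_mean + q.ref_ct_sd * rng.standard_normal()
                ct_rows.append(
                    {"sample_id": sample, "group": group, "gene": "GAPDH",
                     "ct": ref_ct}
                )
                for gene in q.genes:
                    ddct = q.ddct_per_stage[gene] * (stage - 1)
                    noise = (
                        q.noise_sd * rng.standard_normal() if q.noise_sd > 0 else 0.0
                    )
                    ct_rows.append(
                        {
                            "sample_id": sample,
                            "group": group,
                            "gene": gene,
                            "ct": ref_ct + q.baseline_dct + ddct + noise,
                        }
                    )
            for gene in q.genes:
                truth_rows.append(
                    {
                        "breed": breed.name,
                        "group": group,
                        "gene": gene,
                        "ddct": q.ddct_per_stage[gene] * (stage - 1),
                    }
                )
    return pd.DataFrame(ct_rows), pd.DataFrame(truth_rows)


def with_noise_free(spec: SyntheticHerdSpec) -> SyntheticHerdSpec:
    """Copy of ``spec`` with every noise source zeroed (for exactness tests)."""
    breeds = []
    for b in spec.breeds:
        breeds.append(
            replace(
                b,
                growth=replace(b.growth, cv_asymptote=0.0, cv_measurement=0.0),
                traits={
                    t: replace(r, sd=0.0) for t, r in b.traits.items()
                },
                qpcr=replace(b.qpcr, noise_sd=0.0),
            )
        )
    return replace(spec, breeds=tuple(breeds))
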