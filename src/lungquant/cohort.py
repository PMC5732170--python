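"""Feature-level synthetic cohorts with the statistical structure the
mutation-prediction analysis assumes.

Each subject carries exemplar composite features, a peritumoral parenchyma
summary, clinical covariates and disease-free survival.  The EGFR label
follows a logistic model on the percent-scale Y and G exemplar shares,
never-smoker status and the fibrosis fraction, with the reported effect
directions: odds of an EGFR mutation rise with Y and G and with never-smoker
status, and fall with peritumoral fibrosis.

Exemplar shares are drawn from scaled Beta distributions (Y, G, P, B, C);
V-I-R-O is the remainder ``100 - (Y+P) - (B+C+G)`` so the composite partition
identity holds exactly, and is split into V, I, R, O by fixed proportions.
Draws whose ground-glass shares would exceed the whole nodule are rejected
and redrawn (rare under the defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exemplars import CANONICAL_COLORS, CompositeFeatures, Glyph
from .parenchyma import ParenchymaSummary

__all__ = ["BetaSpec", "CohortGenParams", "SubjectRecord", "simulate_feature_cohort",
           "cohort_to_frame"]


@dataclass(frozen=True)
class BetaSpec:
    """A scaled Beta draw: ``scale * Beta(a, b)``."""

    a: float
    b: float
    scale: float = 100.0

    @property
    def mean(self) -> float:
        return self.scale * self.a / (self.a + self.b)

    @property
    def var(self) -> float:
        a, b = self.a, self.b
        return self.scale**2 * a * b / ((a + b) ** 2 * (a + b + 1))

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.scale * rng.beta(self.a, self.b, size=size)


#: Default generative distributions (percent of nodule volume for exemplar
#: shares; fraction of shell for fibrosis and low attenuation).
DEFAULT_FEATURES: dict[str, BetaSpec] = {
    "y": BetaSpec(2.0, 8.0, 100.0),       # mean 20 %
    "g": BetaSpec(2.0, 9.0, 100.0),       # mean ~18 %
    "p": BetaSpec(2.0, 18.0, 50.0),       # mean 5 %
    "b": BetaSpec(2.0, 18.0, 40.0),       # mean 4 %
    "c": BetaSpec(2.0, 18.0, 40.0),       # mean 4 %
    "fibrosis": BetaSpec(1.5, 8.5, 1.0),  # mean 0.15
    "low_attenuation": BetaSpec(1.5, 8.5, 1.0),
}

#: Fixed split of the V-I-R-O remainder into its four colours.
VIRO_SPLIT = {"V": 0.35, "I": 0.25, "R": 0.25, "O": 0.15}


@dataclass(frozen=True)
class CohortGenParams:
    """Generative parameters of the synthetic cohort.

    Logistic coefficients are per percent for the exemplar shares and per
    unit fraction for fibrosis; the defaults give an EGFR prevalence near the
    ~13 % seen in surgical adenocarcinoma series while preserving the
    reported effect directions.
    """

    n: int = 200
    beta0: float = -3.8
    beta_Y: float = 0.06
    beta_G: float = 0.05
    beta_never_smoker: float = 2.0
    beta_fibrosis: float = -4.0
    smoking_probs: tuple[float, float, float] = (0.12, 0.65, 0.23)  # never/former/current
    feature_distributions: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    survival_scale_by_risk_group: dict = field(
        default_factory=lambda: {"G": 80.0, "I": 48.0, "P": 24.0}
    )
    censor_horizon_months: float = 60.0
    kras_prob_wildtype: float = 0.44
    tp53_prob: float = 0.41
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.smoking_probs) - 1.0) > 1e-9 or any(
            p < 0 for p in self.smoking_probs
        ):
            raise ValueError("smoking_probs must be a probability vector over "
                             "(never, former, current)")
        if any(s <= 0 for s in self.survival_scale_by_risk_group.values()):
            raise ValueError("survival scales must be positive")


@dataclass
class SubjectRecord:
    """One synthetic subject: covariates, mutations, imaging features, DFS."""

    id: str
    gender: str
    age: float
    smoking: str
    egfr: bool
    kras: bool
    tp53: bool
    other_mutations: list[str]
    egfr_subtype: str  # L858R, exon19del, or none
    nodule_volume_cc: float
    glyph: Glyph
    composites: CompositeFeatures
    parenchyma: ParenchymaSummary
    risk_group: str
    dfs_time: float
    dfs_event: bool
    stage: str

    def __post_init__(self) -> None:
        if self.egfr and self.kras:
            warnings.warn(f"subject {self.id}: EGFR and KRAS are expected to be "
                          "mutually exclusive")
        if self.dfs_time < 0:
            raise ValueError("dfs_time must be non-negative")


def _risk_group_from_viro(viro: float) -> str:
    # more solid texture = worse prognosis
    if viro <= 35.0:
        return "G"
    if viro >= 70.0:
        return "P"
    return "I"


def simulate_feature_cohort(params: CohortGenParams) -> list[SubjectRecord]:
    """Draw a cohort of :class:`SubjectRecord` under the generative model.

    Deterministic for a fixed ``params.rng_seed``.  EGFR labels are Bernoulli
    with ``logit = beta0 + beta_Y*Y + beta_G*G + beta_never*1[never] +
    beta_fibrosis*fibrosis``; KRAS is drawn only among EGFR-wild-type
    subjects so the two stay mutually exclusive; DFS is exponential per risk
    group with administrative censoring at the horizon.
    """
    rng = np.random.default_rng(params.rng_seed)
    fd = params.feature_distributions
    n = params.n

    smoking = rng.choice(["never", "former", "current"], size=n, p=params.smoking_probs)
    gender = rng.choice(["female", "male"], size=n, p=[0.55, 0.45])
    age = np.clip(rng.normal(68.0, 10.0, size=n), 35.0, 91.0)
    nodule_cc = np.exp(rng.normal(np.log(2.2), 0.7, size=n))

    def draw_shares() -> np.ndarray:
        out = np.empty((n, 5))
        todo = np.arange(n)
        while todo.size:
            cand = np.column_stack([fd[k].draw(rng, todo.size) for k in
                                    ("y", "g", "p", "b", "c")])
            ok = cand.sum(axis=1) <= 97.0
            out[todo[ok]] = cand[ok]
            todo = todo[~ok]
        return out

    y, g, p, b, c = draw_shares().T
    yp = y + p
    bcg = b + c + g
    viro = 100.0 - yp - bcg

    fibrosis = fd["fibrosis"].draw(rng, n)
    la = fd["low_attenuation"].draw(rng, n)
    # keep the five-class partition feasible
    squeeze = np.maximum(fibrosis + la, 1.0)
    fibrosis, la = fibrosis / squeeze, la / squeeze

    never = smoking == "never"
    logit = (params.beta0 + params.beta_Y * y + params.beta_G * g
             + params.beta_never_smoker * never + params.beta_fibrosis * fibrosis)
    egfr = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    kras = ~egfr & (rng.random(n) < params.kras_prob_wildtype)
    tp53 = rng.random(n) < params.tp53_prob
    subtype_draw = rng.random(n) < 0.4

    records = []
    for i in range(n):
        glyph_pct = {
            "Y": y[i], "P": p[i], "B": b[i], "C": c[i], "G": g[i],
            **{col: viro[i] * w for col, w in VIRO_SPLIT.items()},
        }
        glyph = Glyph({k: glyph_pct[k] for k in CANONICAL_COLORS})
        comps = CompositeFeatures(viro=viro[i], yp=yp[i], bcg=bcg[i],
                                  y=y[i], g=g[i], y_plus_g=y[i] + g[i])
        summary = ParenchymaSummary(
            fraction_normal=max(1.0 - fibrosis[i] - la[i], 0.0),
            fraction_LA=la[i],
            fraction_GG=0.6 * fibrosis[i],
            fraction_reticular=0.3 * fibrosis[i],
            fraction_HC=0.1 * fibrosis[i],
        )
        group = _risk_group_from_viro(viro[i])
        scale = params.survival_scale_by_risk_group[group]
        t = rng.exponential(scale)
        dfs_time = min(t, params.censor_horizon_months)
        records.append(
            SubjectRecord(
                id=f"S{i:04d}",
                gender=str(gender[i]),
                age=float(age[i]),
                smoking=str(smoking[i]),
                egfr=bool(egfr[i]),
                kras=bool(kras[i]),
                tp53=bool(tp53[i]),
                other_mutations=[],
                egfr_subtype=("L858R" if subtype_draw[i] else "exon19del")
                if egfr[i] else "none",
                nodule_volume_cc=float(nodule_cc[i]),
                glyph=glyph,
                composites=comps,
                parenchyma=summary,
                risk_group=group,
                dfs_time=float(dfs_time),
                dfs_event=bool(t <= params.censor_horizon_months),
                stage="I",
            )
        )
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the cohort CSV layout.

    Columns: id, gender, age, smoking, egfr, kras, tp53, egfr_subtype,
    nodule_cc, the nine glyph percentages (lower-case colour letters),
    viro/yp/bcg/y_plus_g composites, frac_N/frac_LA/frac_GG/frac_R/frac_HC,
    fibrosis, low_attenuation, risk_group, dfs_time, dfs_event, stage.
    """
    rows = []
    for r in records:
        row = {
            "id": r.id, "gender": r.gender, "age": r.age, "smoking": r.smoking,
            "egfr": int(r.egfr), "kras": int(r.kras), "tp53": int(r.tp53),
            "egfr_subtype": r.egfr_subtype, "nodule_cc": r.nodule_volume_cc,
        }
        row.update({c.lower(): r.glyph[c] for c in CANONICAL_COLORS})
        row.update({
            "viro": r.composites.viro, "yp": r.composites.yp,
            "bcg": r.composites.bcg, "y_plus_g": r.composites.y_plus_g,
            "frac_N": r.parenchyma.fraction_normal,
            "frac_LA": r.parenchyma.fraction_LA,
            "frac_GG": r.parenchyma.fraction_GG,
            "frac_R": r.parenchyma.fraction_reticular,
            "frac_HC": r.parenchyma.fraction_HC,
            "fibrosis": r.parenchyma.fibrosis,
            "low_attenuation": r.parenchyma.low_attenuation,
            "risk_group": r.risk_group,
            "dfs_time": r.dfs_time, "dfs_event": int(r.dfs_event),
            "stage": r.stage,
        })
        rows.append(row)
    return pd.DataFrame(rows)
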