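"""Synthetic two-group, two-session cohort generator.

Generates a complete synthetic study — ground-truth agent parameters,
simulated task behaviour for both sessions, and a clinical/covariate table —
so that every downstream stage (fitting, model comparison, group inference,
reliability, prediction) can be exercised without participant data.

Defaults emulate the real study's structure: healthy-control and
substance-use groups with the published parameter means/SDs per group and
session, cross-session parameter correlations at the published test-retest
levels, covariate distributions (age, sex, premorbid IQ), substance-class
strata, and symptom scores (DAST/PHQ/OASIS) with plantable
parameter-symptom correlation structure.

Parameter distributions are Gaussian in estimation space (log/logit) and
moment-matched to the published native-space means/SDs, so positivity and
(0, 1) bounds hold without truncation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fitting import to_estimation_space, to_native_space
from .model import AgentParams
from .task import TaskSchedule, sample_schedule, simulate_agent

__all__ = [
    "CohortSpec",
    "SyntheticStudy",
    "generate_cohort",
    "plant_effect",
    "pooled_reference_moments",
    "draw_parameter_vectors",
    "match_moments",
]

PARAMS = ("alpha", "c_r", "eta_win", "eta_loss", "a_0")

#: Native-space parameter means/SDs by (group, session) in the full sample.
PARAM_MOMENTS_NATIVE = {
    "alpha": {
        ("hc", "baseline"): (2.57, 0.92),
        ("sud", "baseline"): (2.20, 0.58),
        ("hc", "followup"): (2.71, 0.95),
        ("sud", "followup"): (2.44, 0.86),
    },
    "c_r": {
        ("hc", "baseline"): (4.30, 1.47),
        ("sud", "baseline"): (4.25, 1.50),
        ("hc", "followup"): (4.50, 1.45),
        ("sud", "followup"): (4.71, 1.49),
    },
    "eta_win": {
        ("hc", "baseline"): (0.47, 0.12),
        ("sud", "baseline"): (0.50, 0.13),
        ("hc", "followup"): (0.49, 0.13),
        ("sud", "followup"): (0.51, 0.15),
    },
    "eta_loss": {
        ("hc", "baseline"): (0.43, 0.13),
        ("sud", "baseline"): (0.39, 0.15),
        ("hc", "followup"): (0.39, 0.15),
        ("sud", "followup"): (0.35, 0.16),
    },
    "a_0": {
        ("hc", "baseline"): (0.72, 0.27),
        ("sud", "baseline"): (0.79, 0.29),
        ("hc", "followup"): (0.76, 0.31),
        ("sud", "followup"): (0.82, 0.25),
    },
}

#: Full-sample group sizes at follow-up.
GROUP_N = {"hc": 48, "sud": 83}

#: Pooled cross-session test-retest correlations (estimation space).
CROSS_SESSION_CORR = {"alpha": 0.32, "c_r": 0.54, "eta_win": 0.35, "eta_loss": 0.43, "a_0": 0.25}

#: Covariate moments per group: age mean/SD, male fraction, premorbid IQ mean/SD.
COVARIATES = {
    "hc": {"age": (32.19, 11.19), "male_p": 0.46, "wrat": (63.78, 4.61)},
    "sud": {"age": (35.32, 9.46), "male_p": 0.42, "wrat": (58.45, 6.31)},
}

#: Symptom score means/SDs per (group, session); integer, floor/ceiling clipped.
SYMPTOMS = {
    "dast": {
        ("hc", "baseline"): (0.12, 0.39),
        ("hc", "followup"): (0.45, 0.55),
        ("sud", "baseline"): (7.55, 2.17),
        ("sud", "followup"): (2.72, 3.01),
    },
    "phq": {
        ("hc", "baseline"): (0.88, 1.33),
        ("hc", "followup"): (1.08, 1.81),
        ("sud", "baseline"): (6.84, 6.11),
        ("sud", "followup"): (3.35, 4.69),
    },
    "oasis": {
        ("hc", "baseline"): (1.48, 2.01),
        ("hc", "followup"): (1.39, 2.27),
        ("sud", "baseline"): (5.99, 4.74),
        ("sud", "followup"): (3.74, 4.49),
    },
}
SYMPTOM_MAX = {"dast": 10, "phq": 27, "oasis": 20}

#: Substance-class stratum frequencies within the SUD group at follow-up.
STRATA_P = {"stimulant": 0.73, "opioid": 0.36, "alcohol": 0.36, "cannabis": 0.28, "sedative": 0.25}

#: Loadings of z-scored estimation-space parameters on per-subject log mean RT:
#: faster responses with higher reward sensitivity and win learning rate,
#: slower with higher loss learning rate and information insensitivity.
RT_LOADINGS = {"alpha": 0.0, "c_r": -0.10, "eta_win": -0.10, "eta_loss": 0.10, "a_0": 0.10}

#: Baseline-to-followup correlation of the latent symptom trajectory.
DAST_STABILITY = 0.30

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _logitnormal_moments(mu: float, sigma: float):
    x = 1.0 / (1.0 + np.exp(-(mu + sigma * _GH_NODES)))
    m = float(np.sum(_GH_WEIGHTS * x))
    v = float(np.sum(_GH_WEIGHTS * (x - m) ** 2))
    return m, np.sqrt(v)


def match_moments(name: str, mean: float, sd: float):
    """(mu, sigma) of the estimation-space Gaussian whose native-space
    distribution has the requested mean and SD.

    Closed form for log-space parameters (lognormal); numeric inversion via
    Gauss-Hermite quadrature for logit-space learning rates.
    """
    if name in ("alpha", "c_r", "a_0"):
        s2 = np.log1p((sd / mean) ** 2)
        return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))
    from scipy.optimize import least_squares

    def resid(x):
        m, s = _logitnormal_moments(x[0], x[1])
        return [m - mean, s - sd]

    x0 = [float(np.log(mean / (1 - mean))), float(sd / (mean * (1 - mean)))]
    sol = least_squares(resid, x0, bounds=([-10, 1e-4], [10, 10]))
    return float(sol.x[0]), float(sol.x[1])


def pooled_reference_moments(session: str = "followup"):
    """Native-space parameter means/SDs pooled over both groups at the
    published group sizes (between-group spread included in the SD)."""
    w = np.array([GROUP_N["hc"], GROUP_N["sud"]], dtype=float)
    w /= w.sum()
    means, sds = {}, {}
    for p in PARAMS:
        ms = np.array([PARAM_MOMENTS_NATIVE[p][(g, session)][0] for g in ("hc", "sud")])
        ss = np.array([PARAM_MOMENTS_NATIVE[p][(g, session)][1] for g in ("hc", "sud")])
        mean = float(np.sum(w * ms))
        second = float(np.sum(w * (ms**2 + ss**2)))
        means[p] = mean
        sds[p] = float(np.sqrt(second - mean**2))
    return means, sds


def draw_parameter_vectors(n: int, means: dict, sds: dict, rng) -> list:
    """Draw ``n`` independent agents from estimation-space Gaussians
    moment-matched to the given native means/SDs."""
    cols = {}
    for p in PARAMS:
        mu, sigma = match_moments(p, means[p], sds[p])
        cols[p] = to_native_space(p, rng.normal(mu, sigma, size=n))
    return [
        AgentParams(cols["alpha"][i], cols["c_r"][i], cols["eta_win"][i], cols["eta_loss"][i], cols["a_0"][i])
        for i in range(n)
    ]


def _default_means_est():
    means = {}
    sds = {}
    for p in PARAMS:
        for key, (m, s) in PARAM_MOMENTS_NATIVE[p].items():
            mu, sigma = match_moments(p, m, s)
            means[(p,) + key] = mu
            sds[(p,) + key] = sigma
    return means, sds


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic two-session, two-group study.

    ``means_est`` / ``sds_est`` hold estimation-space Gaussian parameters
    keyed by (parameter, group, session); defaults are moment-matched to the
    published full-sample values.  ``planted`` records effect descriptors
    applied by :func:`plant_effect`.
    """

    n_hc: int = GROUP_N["hc"]
    n_sud: int = GROUP_N["sud"]
    means_est: dict = field(default_factory=lambda: _default_means_est()[0])
    sds_est: dict = field(default_factory=lambda: _default_means_est()[1])
    cross_session_corr: dict = field(default_factory=lambda: dict(CROSS_SESSION_CORR))
    planted: tuple = ()
    simulate_behavior: bool = True
    dropout: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_sud < 2:
            raise ValueError("group sizes must be >= 2")
        for p, r in self.cross_session_corr.items():
            if not -1 < r < 1:
                raise ValueError(f"cross-session correlation for {p} must be in (-1, 1)")
        for k, s in self.sds_est.items():
            if s <= 0:
                raise ValueError(f"SD for {k} must be > 0")

    def to_yaml(self, path) -> None:
        payload = {
            "n_hc": self.n_hc,
            "n_sud": self.n_sud,
            "means_est": {"|".join(k): v for k, v in self.means_est.items()},
            "sds_est": {"|".join(k): v for k, v in self.sds_est.items()},
            "cross_session_corr": dict(self.cross_session_corr),
            "planted": [dict(e) for e in self.planted],
            "simulate_behavior": self.simulate_behavior,
            "dropout": self.dropout,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["means_est"] = {tuple(k.split("|")): v for k, v in payload["means_est"].items()}
        payload["sds_est"] = {tuple(k.split("|")): v for k, v in payload["sds_est"].items()}
        payload["planted"] = tuple(payload.get("planted", ()))
        return cls(**payload)


_PLANT_KINDS = ("equalize_groups", "group", "session", "symptom_corr", "delta_corr")


def _plant_key(effect: dict):
    kind = effect["kind"]
    if kind == "equalize_groups":
        return (kind,)
    if kind in ("group", "session"):
        return (kind, effect["param"])
    return (kind, effect["param"], effect.get("stratum"))


def plant_effect(spec: CohortSpec, effect: dict) -> CohortSpec:
    """Return a spec with one named effect planted.

    Supported kinds:

    - ``equalize_groups``: erase all group differences (SUD means := HC means).
    - ``group``: add ``offset`` (estimation space) to the SUD-group mean of
      ``param`` in both sessions.
    - ``session``: add ``drift`` (estimation space) to the follow-up mean of
      ``param`` in both groups.
    - ``symptom_corr``: plant correlation ``r`` between ``param`` at
      ``param_session`` (default baseline) and follow-up DAST, within
      ``stratum`` (or all SUDs when ``stratum`` is None).
    - ``delta_corr``: plant correlation ``r`` between baseline-to-follow-up
      change in ``param`` and change in DAST, within ``stratum``.

    Plants compose; re-planting the same cell raises ``ValueError``.
    """
    if effect.get("kind") not in _PLANT_KINDS:
        raise ValueError(f"unknown effect kind: {effect.get('kind')!r}")
    key = _plant_key(effect)
    if any(_plant_key(e) == key for e in spec.planted):
        raise ValueError(f"effect already planted for {key}")
    return CohortSpec(
        n_hc=spec.n_hc,
        n_sud=spec.n_sud,
        means_est=dict(spec.means_est),
        sds_est=dict(spec.sds_est),
        cross_session_corr=dict(spec.cross_session_corr),
        planted=spec.planted + (dict(effect),),
        simulate_behavior=spec.simulate_behavior,
        dropout=spec.dropout,
        seed=spec.seed,
    )


@dataclass
class SyntheticStudy:
    """Outputs of one synthetic study (all tables tidy DataFrames)."""

    schedule: TaskSchedule
    behavior: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def _effective_means(spec: CohortSpec) -> dict:
    means = dict(spec.means_est)
    for e in spec.planted:
        if e["kind"] == "equalize_groups":
            for p in PARAMS:
                for ses in ("baseline", "followup"):
                    means[(p, "sud", ses)] = means[(p, "hc", ses)]
    for e in spec.planted:
        if e["kind"] == "group":
            for ses in ("baseline", "followup"):
                means[(e["param"], "sud", ses)] += e["offset"]
        elif e["kind"] == "session":
            for g in ("hc", "sud"):
                means[(e["param"], g, "followup")] += e["drift"]
    return means


def generate_cohort(spec: CohortSpec) -> SyntheticStudy:
    """Generate a full synthetic study from a cohort spec.

    Per subject, session-pair parameter vectors are drawn from bivariate
    Gaussians in estimation space with the spec's means/SDs and
    cross-session correlations (independent across parameters), behaviour is
    simulated with the shared seeded schedule, and symptom scores are built
    from a Gaussian latent with the planted correlation structure, then
    rounded and clipped to the instrument range.  Deterministic under
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = sample_schedule(int(rng.integers(2**31 - 1)))
    means = _effective_means(spec)

    n_total = spec.n_hc + spec.n_sud
    groups = ["hc"] * spec.n_hc + ["sud"] * spec.n_sud
    subject_ids = [f"S{i + 1:04d}" for i in range(n_total)]

    # latent parameter draws, estimation space: dict param -> (n, 2 sessions)
    z_est = {}
    for p in PARAMS:
        rho = spec.cross_session_corr[p]
        x = np.empty((n_total, 2))
        for gi, g in enumerate(("hc", "sud")):
            mask = np.array([grp == g for grp in groups])
            n_g = int(mask.sum())
            mu = np.array([means[(p, g, "baseline")], means[(p, g, "followup")]])
            s = np.array([spec.sds_est[(p, g, "baseline")], spec.sds_est[(p, g, "followup")]])
            cov = np.array([[s[0] ** 2, rho * s[0] * s[1]], [rho * s[0] * s[1], s[1] ** 2]])
            x[mask] = rng.multivariate_normal(mu, cov, size=n_g)
        z_est[p] = x

    # strata flags for SUD subjects
    strata = {}
    for name, prob in STRATA_P.items():
        flags = np.zeros(n_total, dtype=bool)
        flags[spec.n_hc:] = rng.random(spec.n_sud) < prob
        strata[name] = flags

    clinical = _make_clinical(spec, rng, groups, subject_ids, strata, z_est, means)
    truth = _make_truth(subject_ids, groups, strata, z_est)

    behavior = pd.DataFrame()
    if spec.simulate_behavior:
        returning = np.ones(n_total, dtype=bool)
        if spec.dropout:
            # 83 of 147 substance users returned in the real study
            returning[spec.n_hc:] = rng.random(spec.n_sud) < (83.0 / 147.0)
        # per-subject RT structure from z-scored parameters
        tables = []
        for i, sid in enumerate(subject_ids):
            for si, ses in enumerate(("baseline", "followup")):
                if ses == "followup" and not returning[i]:
                    continue
                native = {p: float(to_native_space(p, z_est[p][i, si])) for p in PARAMS}
                params = AgentParams(
                    native["alpha"], native["c_r"], native["eta_win"], native["eta_loss"], native["a_0"]
                )
                zscore = 0.0
                for p in PARAMS:
                    g = groups[i]
                    zscore += RT_LOADINGS[p] * (
                        (z_est[p][i, si] - means[(p, g, ses)]) / spec.sds_est[(p, g, ses)]
                    )
                rt_mu = np.log(0.55) + zscore + rng.normal(0.0, 0.15)
                tables.append(
                    simulate_agent(
                        params,
                        schedule,
                        seed=int(rng.integers(2**31 - 1)),
                        subject_id=sid,
                        session=ses,
                        rt_mean_log=rt_mu,
                    )
                )
        behavior = pd.concat(tables, ignore_index=True)
        clinical = clinical.assign(returned=returning)

    return SyntheticStudy(schedule=schedule, behavior=behavior, clinical=clinical, truth=truth, spec=spec)


def _make_truth(subject_ids, groups, strata, z_est) -> pd.DataFrame:
    rows = []
    for i, sid in enumerate(subject_ids):
        for si, ses in enumerate(("baseline", "followup")):
            row = {"subject_id": sid, "group": groups[i], "session": ses}
            for p in PARAMS:
                row[f"{p}_est"] = z_est[p][i, si]
                row[p] = float(to_native_space(p, z_est[p][i, si]))
            for name, flags in strata.items():
                row[name] = bool(flags[i])
            rows.append(row)
    return pd.DataFrame(rows)


def _symptom_draw(rng, n, mean, sd, max_val, latent=None):
    z = latent if latent is not None else rng.standard_normal(n)
    raw = mean + sd * z
    return np.clip(np.round(raw), 0, max_val).astype(int), z


def _make_clinical(spec, rng, groups, subject_ids, strata, z_est, means) -> pd.DataFrame:
    n = len(subject_ids)
    hc_mask = np.array([g == "hc" for g in groups])

    age = np.where(
        hc_mask,
        rng.normal(*COVARIATES["hc"]["age"], size=n),
        rng.normal(*COVARIATES["sud"]["age"], size=n),
    )
    age = np.clip(age, 18, 55)
    male = np.where(
        hc_mask,
        rng.random(n) < COVARIATES["hc"]["male_p"],
        rng.random(n) < COVARIATES["sud"]["male_p"],
    ).astype(int)
    wrat = np.where(
        hc_mask,
        rng.normal(*COVARIATES["hc"]["wrat"], size=n),
        rng.normal(*COVARIATES["sud"]["wrat"], size=n),
    )

    # latent DAST trajectory with planted parameter links (SUD group only)
    dast_base_z = rng.standard_normal(n)
    planted_signal = np.zeros(n)
    ssq = np.full(n, DAST_STABILITY**2)
    sd_b = np.where(hc_mask, SYMPTOMS["dast"][("hc", "baseline")][1], SYMPTOMS["dast"][("sud", "baseline")][1])
    sd_f = np.where(hc_mask, SYMPTOMS["dast"][("hc", "followup")][1], SYMPTOMS["dast"][("sud", "followup")][1])
    sd_delta = np.sqrt(sd_b**2 + sd_f**2 - 2 * DAST_STABILITY * sd_b * sd_f)
    for e in spec.planted:
        if e["kind"] not in ("symptom_corr", "delta_corr"):
            continue
        p = e["param"]
        stratum = e.get("stratum")
        mask = ~hc_mask if stratum is None else strata[stratum]
        if e["kind"] == "symptom_corr":
            ses = e.get("param_session", "baseline")
            si = 0 if ses == "baseline" else 1
            mu = np.array([means[(p, groups[i], ses)] for i in range(n)])
            s = np.array([spec.sds_est[(p, groups[i], ses)] for i in range(n)])
            z = (z_est[p][:, si] - mu) / s
            r = e["r"]
        else:
            mu_d = np.array(
                [means[(p, groups[i], "followup")] - means[(p, groups[i], "baseline")] for i in range(n)]
            )
            s_d = np.array(
                [
                    np.sqrt(
                        spec.sds_est[(p, groups[i], "baseline")] ** 2
                        + spec.sds_est[(p, groups[i], "followup")] ** 2
                        - 2
                        * spec.cross_session_corr[p]
                        * spec.sds_est[(p, groups[i], "baseline")]
                        * spec.sds_est[(p, groups[i], "followup")]
                    )
                    for i in range(n)
                ]
            )
            z = (z_est[p][:, 1] - z_est[p][:, 0] - mu_d) / s_d
            # compensate for the attenuation from differencing the DAST scale
            r = e["r"] * sd_delta / sd_f
            r = np.where(np.abs(r) < 0.99, r, np.sign(r) * 0.99)
        planted_signal += np.where(mask, r * z, 0.0)
        ssq += np.where(mask, np.asarray(r) ** 2, 0.0)
    if np.any(ssq > 1.0):
        raise ValueError("planted correlations are jointly infeasible (sum of squares > 1)")
    dast_fu_z = DAST_STABILITY * dast_base_z + planted_signal + np.sqrt(1.0 - ssq) * rng.standard_normal(n)

    out = {"subject_id": subject_ids, "group": groups, "age": age, "sex_male": male, "wrat": wrat}
    for name, flags in strata.items():
        out[name] = flags
    for score in ("dast", "phq", "oasis"):
        for ses in ("baseline", "followup"):
            m = np.where(hc_mask, SYMPTOMS[score][("hc", ses)][0], SYMPTOMS[score][("sud", ses)][0])
            s = np.where(hc_mask, SYMPTOMS[score][("hc", ses)][1], SYMPTOMS[score][("sud", ses)][1])
            if score == "dast":
                z = dast_base_z if ses == "baseline" else dast_fu_z
            else:
                z = rng.standard_normal(n)
            vals = np.clip(np.round(m + s * z), 0, SYMPTOM_MAX[score]).astype(int)
            out[f"{score}_{ses}"] = vals
    return pd.DataFrame(out)
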