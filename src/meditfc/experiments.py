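"""Calibration experiments on synthetic cohorts.

These are the package's standing sanity experiments: they regenerate
synthetic data from scratch, run the pipeline, and measure whether the
known ground truth is recovered. The test suite and the reproduction
script both call into this module so the numbers they report come from
one code path.

Problem sizes (segment lengths, cohort sizes, seed counts) are chosen
for desk-scale runs: one 60 s segment per state gives six 10 s epochs,
enough to resolve the coupling effects the generator plants while a
whole experiment stays in the minutes range on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import CLASSIFIER_NAMES, crossvalidate
from .features import build_feature_table, extract_cohort_features, extract_features
from .group_stats import compare_groups
from .synthetic import (
    SynthConfig,
    generate_cohort,
    generate_recording,
    subject_rng,
    uniform_band_coupling,
)

#: Segment length (s) per state for calibration cohorts: 6 epochs of 10 s.
CALIBRATION_STATE_SECONDS = 60.0


def _single_state_config(
    kappa_by_group: dict[str, float],
    *,
    n_per_group: dict[str, int],
    noise_sd: float,
    seed: int,
    state: str = "meditation",
    state_seconds: float = CALIBRATION_STATE_SECONDS,
) -> SynthConfig:
    coupling = {}
    for group, kappa in kappa_by_group.items():
        coupling.update(
            {(group, s, b): kappa for (g, s, b) in uniform_band_coupling(kappa) if g == group}
        )
    return SynthConfig(
        n_per_group={g: n_per_group.get(g, 0) for g in ("LTM", "STM", "NM")},
        state_durations={state: state_seconds},
        band_coupling=coupling,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# coupling -> PLV recovery


def plv_vs_coupling(
    *,
    kappas: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 20,
    noise_sd: float = 0.0,
    state_seconds: float = CALIBRATION_STATE_SECONDS,
    band: str = "alpha",
    master_seed: int = 0,
) -> pd.DataFrame:
    """Mean inter-hemispheric alpha PLV (and |r|) per planted kappa.

    One single-subject recording per (kappa, seed): a 60 s meditation
    segment with the same kappa in every band.
    """
    rows = []
    for kappa in kappas:
        config = SynthConfig(
            n_per_group={"NM": 1},
            state_durations={"meditation": state_seconds},
            band_coupling=uniform_band_coupling(kappa),
            noise_sd=noise_sd,
        )
        for s in range(n_seeds):
            rec = generate_recording(
                config, "NM", "NM01", subject_rng(master_seed + s, "NM", 0)
            )
            feats = extract_features(rec)
            cell = feats[feats["band"] == band]
            rows.append(
                {
                    "kappa": kappa,
                    "seed": s,
                    "plv": float(cell["plv"].mean()),
                    "abs_r": float(cell["r"].abs().mean()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CouplingRecovery:
    spearman_plv: float
    spearman_abs_r: float
    plv_at_full_coupling: float
    mean_plv_by_kappa: dict[float, float]


def coupling_recovery_summary(df: pd.DataFrame) -> CouplingRecovery:
    """Monotonicity (Spearman of per-seed PLV against kappa) and the
    PLV reached at kappa = 1."""
    rho_plv = float(stats.spearmanr(df["kappa"], df["plv"]).statistic)
    rho_r = float(stats.spearmanr(df["kappa"], df["abs_r"]).statistic)
    by_kappa = df.groupby("kappa")["plv"].mean()
    return CouplingRecovery(
        spearman_plv=rho_plv,
        spearman_abs_r=rho_r,
        plv_at_full_coupling=float(by_kappa.loc[df["kappa"].max()]),
        mean_plv_by_kappa={float(k): float(v) for k, v in by_kappa.items()},
    )


# ---------------------------------------------------------------------------
# directional state effect: meditation/transmission vs baseline


def state_direction_experiment(
    *,
    n_seeds: int = 40,
    state_seconds: float = CALIBRATION_STATE_SECONDS,
    noise_sd: float = 0.3,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Per seed, does the planted state effect reproduce directionally?

    Uses the default coupling map (meditation and transmission more
    strongly coupled than baseline) for an LTM subject, and records
    whether r, PLV and CC rise while SP falls in each elevated state
    relative to baseline, averaging features over the four bands.
    """
    config = SynthConfig(
        n_per_group={"LTM": 1},
        state_durations={
            "baseline": state_seconds,
            "meditation": state_seconds,
            "transmission": state_seconds,
        },
        noise_sd=noise_sd,
    )
    rows = []
    for s in range(n_seeds):
        rec = generate_recording(config, "LTM", "LTM01", subject_rng(master_seed + s, "LTM", 0))
        feats = extract_features(rec)
        per_state = feats.groupby("state")[["r", "plv", "cc", "sp"]].mean()
        for state in ("meditation", "transmission"):
            rows.append(
                {
                    "seed": s,
                    "state": state,
                    "r_up": per_state.loc[state, "r"] > per_state.loc["baseline", "r"],
                    "plv_up": per_state.loc[state, "plv"] > per_state.loc["baseline", "plv"],
                    "cc_up": per_state.loc[state, "cc"] > per_state.loc["baseline", "cc"],
                    "sp_down": per_state.loc[state, "sp"] < per_state.loc["baseline", "sp"],
                }
            )
    df = pd.DataFrame(rows)
    df["all_directions"] = df[["r_up", "plv_up", "cc_up", "sp_down"]].all(axis=1)
    return df


# ---------------------------------------------------------------------------
# classifier calibration: null and separated cohorts


def _meditation_accuracy(
    config: SynthConfig, classifiers: tuple[str, ...], seed: int
) -> dict[str, float]:
    cohort = generate_cohort(config)
    feats = extract_cohort_features(cohort)
    table = build_feature_table(feats, "statewise", "meditation")
    out = {}
    for name in classifiers:
        res = crossvalidate(
            table, ("LTM", "NM"), name, seed, layout="statewise", fixed_factor="meditation"
        )
        out[name] = res.mean_accuracy
    return out


def null_classifier_calibration(
    *,
    n_seeds: int = 20,
    n_per_group: int = 10,
    kappa: float = 0.4,
    noise_sd: float = 0.3,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Accuracies on cohorts with no group effect (equal kappa everywhere).

    Mean accuracy should sit at the chance rate; the independent unit for
    the chance band is the subject, not the epoch.
    """
    rows = []
    for s in range(n_seeds):
        config = _single_state_config(
            {"LTM": kappa, "NM": kappa},
            n_per_group={"LTM": n_per_group, "NM": n_per_group},
            noise_sd=noise_sd,
            seed=master_seed + s,
        )
        accs = _meditation_accuracy(config, classifiers, master_seed + s)
        rows.append({"seed": s, **accs})
    return pd.DataFrame(rows)


def separated_classifier_experiment(
    *,
    n_seeds: int = 10,
    n_per_group: int = 10,
    kappa_high: float = 0.7,
    kappa_low: float = 0.3,
    noise_sd: float = 0.1,
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Accuracies on strongly separated cohorts (kappa gap 0.4, low noise)."""
    rows = []
    for s in range(n_seeds):
        config = _single_state_config(
            {"LTM": kappa_high, "NM": kappa_low},
            n_per_group={"LTM": n_per_group, "NM": n_per_group},
            noise_sd=noise_sd,
            seed=master_seed + s,
        )
        accs = _meditation_accuracy(config, classifiers, master_seed + s)
        rows.append({"seed": s, **accs})
    return pd.DataFrame(rows)


def chance_band(p0: float, n_independent: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial band around the chance rate ``p0``
    for a mean over ``n_independent`` Bernoulli units."""
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p0 * (1 - p0) / n_independent)
    return p0 - half, p0 + half


# ---------------------------------------------------------------------------
# type-I error of the group comparison


def type1_error_rate(
    *,
    n_sims: int = 1000,
    n_per_group: int = 10,
    alpha: float = 0.05,
    master_seed: int = 0,
) -> float:
    """Fraction of null simulations (both groups drawn from the same
    normal distribution of subject-level features) reaching p < alpha."""
    rng = np.random.default_rng(master_seed)
    hits = 0
    for _ in range(n_sims):
        a = rng.standard_normal(n_per_group)
        b = rng.standard_normal(n_per_group)
        gc = compare_groups(
            a, b, measure="r", band="alpha", state="meditation", pair=("LTM", "NM")
        )
        if gc.p_value < alpha:
            hits += 1
    return hits / n_sims


# ---------------------------------------------------------------------------
# full study-design cohort


def study_cohort_comparison(
    *,
    master_seed: int = 0,
    state_seconds: float = CALIBRATION_STATE_SECONDS,
    noise_sd: float = 0.3,
) -> pd.DataFrame:
    """State-wise classifier grid on a cohort with the study's group sizes
    (LTM 13, STM 11, NM 10) and the default group/state coupling map,
    at calibration segment lengths."""
    from .classification import run_full_comparison

    config = SynthConfig(
        state_durations={
            "baseline": state_seconds,
            "meditation": state_seconds,
            "transmission": state_seconds,
        },
        noise_sd=noise_sd,
        seed=master_seed,
    )
    feats = extract_cohort_features(generate_cohort(config))
    return run_full_comparison(feats, master_seed, bands=())


def study_config(
    master_seed: int = 0,
    *,
    state_seconds: float = CALIBRATION_STATE_SECONDS,
    include_post: bool = True,
) -> SynthConfig:
    """The demonstration study design: group sizes LTM 13 / STM 11 / NM 10,
    default coupling map, all four states at calibration length."""
    states = ["baseline", "meditation", "transmission"] + (["post"] if include_post else [])
    return SynthConfig(
        state_durations={s: state_seconds for s in states},
        noise_sd=0.3,
        seed=master_seed,
    )
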