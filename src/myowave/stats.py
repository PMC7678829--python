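"""Repeated-measures statistics and the end-to-end synthetic study driver.

This layer mirrors a within-subject gait study design: a one-way
repeated-measures (RM) ANOVA on the impact input frequency across locomotion
conditions, two-way RM ANOVAs (image region x condition) on peak power and
cumulative frequency per aponeurosis, Bonferroni-corrected pairwise post-hoc
tests, and linear/quadratic least-squares trends of the oscillation metrics
against input frequency with r^2.

ANOVA conventions: the classical univariate within-subject partition with the
subject-by-factor interaction as each main effect's error term and no
sphericity correction (a Greenhouse-Geisser option is provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "TrendFit",
    "rm_anova_one_way",
    "rm_anova_two_way",
    "bonferroni_posthoc",
    "fit_trend",
    "StudyConfig",
    "ConditionSpec",
    "StudyReport",
    "run_synthetic_study",
]


@dataclass
class EffectResult:
    name: str
    ss: float
    df: int
    ss_error: float
    df_error: int
    F: float
    p: float


@dataclass
class RmAnovaResult:
    """Repeated-measures ANOVA table, one entry per effect."""

    effects: list[EffectResult]
    posthoc: pd.DataFrame | None = None

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "effect": e.name, "SS": e.ss, "df": e.df, "SS_error": e.ss_error,
            "df_error": e.df_error, "F": e.F, "p": e.p,
        } for e in self.effects])


def _f_p(ss: float, df: int, ss_err: float, df_err: int) -> tuple[float, float]:
    if df <= 0 or df_err <= 0:
        raise ValueError("degrees of freedom must be positive")
    ms, ms_err = ss / df, ss_err / df_err
    if ms_err == 0:
        if ms == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms / ms_err
    return F, float(sps.f.sf(F, df, df_err))


def rm_anova_one_way(values: np.ndarray | pd.DataFrame) -> RmAnovaResult:
    """One-way RM ANOVA on a complete participant x condition table.

    Classical within-subject partition: ``SS_error = SS_total - SS_condition
    - SS_subject``; ``F = MS_condition / MS_error`` with degrees of freedom
    ``(k-1, (k-1)(n-1))``.  No sphericity correction.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("a complete table with >=2 participants and >=2 "
                         "conditions is required")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = X.shape
    gm = X.mean()
    ss_cond = n * np.sum((X.mean(axis=0) - gm) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - gm) ** 2)
    ss_tot = np.sum((X - gm) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    F, p = _f_p(ss_cond, k - 1, ss_err, (k - 1) * (n - 1))
    return RmAnovaResult([EffectResult("condition", ss_cond, k - 1, ss_err,
                                       (k - 1) * (n - 1), F, p)])


def rm_anova_two_way(values: np.ndarray) -> RmAnovaResult:
    """Two-way fully within-subject RM ANOVA on an (subject, A, B) array.

    Each main effect is tested against its subject-by-factor interaction;
    the A x B interaction is tested against the subject x A x B term.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 3:
        raise ValueError("values must be a (subject, factorA, factorB) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, a, b = X.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("each dimension must have at least two levels")
    gm = X.mean()
    m_s = X.mean(axis=(1, 2))
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)
    m_ab = X.mean(axis=0)

    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_s = a * b * np.sum((m_s - gm) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_tot = np.sum((X - gm) ** 2)
    ss_sab = max(ss_tot - ss_a - ss_b - ss_s - ss_sa - ss_sb - ss_ab, 0.0)

    effects = []
    F, p = _f_p(ss_a, a - 1, ss_sa, (a - 1) * (n - 1))
    effects.append(EffectResult("A", ss_a, a - 1, ss_sa, (a - 1) * (n - 1), F, p))
    F, p = _f_p(ss_b, b - 1, ss_sb, (b - 1) * (n - 1))
    effects.append(EffectResult("B", ss_b, b - 1, ss_sb, (b - 1) * (n - 1), F, p))
    F, p = _f_p(ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (n - 1))
    effects.append(EffectResult("AxB", ss_ab, (a - 1) * (b - 1), ss_sab,
                                (a - 1) * (b - 1) * (n - 1), F, p))
    return RmAnovaResult(effects)


def bonferroni_posthoc(
    values: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni-adjusted p values.

    ``values`` is a participant x level table.  The adjusted p value is
    ``min(1, raw * m)`` with m the number of pairs.  A zero-variance
    difference vector yields p = 1 when the mean difference is also zero and
    is flagged degenerate otherwise.
    """
    X = np.asarray(values, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("factor must have at least two levels")
    if labels is None:
        labels = (list(values.columns) if isinstance(values, pd.DataFrame)
                  else [str(i) for i in range(k)])
    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        diff = X[:, i] - X[:, j]
        degenerate = False
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                raw = 1.0
            else:
                raw = 0.0
                degenerate = True
        else:
            raw = float(sps.ttest_rel(X[:, i], X[:, j]).pvalue)
        adj = min(1.0, raw * m)
        rows.append({
            "level_a": labels[i], "level_b": labels[j], "p_raw": raw,
            "p_adjusted": adj, "significant": adj < alpha,
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    """Least-squares polynomial trend of a metric against input frequency."""

    degree: int
    coefficients: np.ndarray  # intercept first
    r_squared: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                                self.coefficients)


def fit_trend(x: np.ndarray, y: np.ndarray, degree: int) -> TrendFit:
    """Least-squares polynomial fit (degree 1 or 2) with r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(x) < degree + 2:
        raise ValueError("at least degree + 2 points required")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all x values are equal")
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TrendFit(degree, coeffs, min(max(r2, 0.0), 1.0))


# ---------------------------------------------------------------------------
# End-to-end synthetic study
# ---------------------------------------------------------------------------

@dataclass
class ConditionSpec:
    """One locomotion condition of the synthetic study."""

    label: str
    gait: str                     # 'walking' | 'running'
    stride_frequency_hz: float    # high-pass cutoff for displacement spectra
    impact_frequency_hz: float    # injected GRF impact frequency
    oscillation_frequency_hz: float  # injected tissue oscillation frequency
    oscillation_amplitude_mm: float
    stance_duration_s: float
    gait_amplitude_mm: float = 1.0


def default_conditions() -> list[ConditionSpec]:
    """Seven steady-state conditions: walking 0.7/1.4/2.0, running 2-5 m/s.

    Stride-frequency cutoffs follow the reference protocol (1.3-3.1 Hz);
    injected impact and oscillation content increases monotonically with
    speed, emulating the increase of impact frequency (10-20 Hz range) and of
    oscillation frequency content (~5-15 Hz) with faster gait.
    """
    labels = ["walk_0.7", "walk_1.4", "walk_2.0",
              "run_2.0", "run_3.0", "run_4.0", "run_5.0"]
    gaits = ["walking"] * 3 + ["running"] * 4
    stride = [1.3, 1.8, 2.4, 2.6, 2.7, 2.9, 3.1]
    impact = [8.0, 10.0, 11.5, 13.0, 15.0, 17.5, 20.0]
    osc_f = [5.0, 6.5, 8.0, 9.5, 11.0, 13.0, 15.0]
    osc_a = [1.0, 1.1, 1.2, 1.3, 1.5, 1.8, 2.0]
    stance = [0.70, 0.62, 0.55, 0.50, 0.45, 0.42, 0.40]
    return [
        ConditionSpec(l, g, sf, fi, fo, ao, st)
        for l, g, sf, fi, fo, ao, st
        in zip(labels, gaits, stride, impact, osc_f, osc_a, stance)
    ]


@dataclass
class StudyConfig:
    """Design of the synthetic study (participants x conditions x stances)."""

    n_participants: int = 3
    n_stances: int = 4
    conditions: list[ConditionSpec] = field(default_factory=default_conditions)
    frame_rate_hz: float = 80.0
    train_label_stride: int = 20   # manual-labelling cadence (every Nth frame)
    training_conditions: tuple[int, ...] = (4, 5)  # run_3.0, run_4.0
    aponeuroses: tuple[str, ...] = ("superficial", "deep")
    seed: int = 0


@dataclass
class StudyReport:
    """Tables produced by :func:`run_synthetic_study`."""

    input_frequency: pd.DataFrame
    spectra: pd.DataFrame
    anova_input: RmAnovaResult | None
    anova_metrics: dict[tuple[str, str], RmAnovaResult]
    trend_fits: pd.DataFrame
    log: list[str]

    def condition_means(self, column: str) -> pd.Series:
        tbl = (self.input_frequency if column == "input_frequency_hz"
               else self.spectra)
        return tbl.groupby("condition", sort=False)[column].mean()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.input_frequency.to_csv(out / "input_frequency.csv", index=False)
        self.spectra.to_csv(out / "spectra_summary.csv", index=False)
        if self.anova_input is not None:
            self.anova_input.to_dataframe().to_csv(
                out / "anova_input_frequency.csv", index=False)
        for (apo, metric), res in self.anova_metrics.items():
            res.to_dataframe().to_csv(
                out / f"anova_{apo}_{metric}.csv", index=False)
        self.trend_fits.to_csv(out / "trend_fits.csv", index=False)
        (out / "run_log.txt").write_text("\n".join(self.log) + "\n")


def _scene_for(cond: ConditionSpec, participant: int, stance: int,
               rng: np.random.Generator):
    """Boundary specs for one stance-phase image sequence."""
    from .synthetic import DEFAULT_MM_PER_PX_Y, BoundarySpec

    jitter = rng.uniform(-8.0, 8.0)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    sup = BoundarySpec(
        c0=160.0 + jitter, c1=0.03, c2=-4e-5,
        components=[
            (cond.stride_frequency_hz, cond.gait_amplitude_mm, phases[0]),
            (cond.oscillation_frequency_hz, cond.oscillation_amplitude_mm,
             phases[1]),
        ],
    )
    deep = BoundarySpec(
        c0=350.0 + jitter, c1=0.02, c2=-2e-5,
        components=[
            (cond.stride_frequency_hz, cond.gait_amplitude_mm, phases[2]),
            (cond.oscillation_frequency_hz,
             0.9 * cond.oscillation_amplitude_mm, phases[3]),
        ],
    )
    _ = DEFAULT_MM_PER_PX_Y
    return sup, deep


def run_synthetic_study(
    config: StudyConfig | None = None, out_dir: str | Path | None = None
) -> StudyReport:
    """Simulate the full study and run the complete analysis pipeline.

    For every participant and condition the driver generates stance-phase
    ultrasound sequences (with known injected oscillations), a GRF trace with
    known impact timing, trains a per-participant ASM on ground-truth labels
    of every ``train_label_stride``-th frame of the two designated training
    conditions, segments all sequences, computes displacement spectra and
    impact input frequencies, and finally runs the RM ANOVAs, post-hoc tests
    and trend fits.  Identical configs (same seed) give identical reports.
    """
    from .asm import LandmarkShape, segment_sequence, train_shape_model
    from .kinetics import analyze_force_trace
    from .spectra import (REGIONS, summarize_displacement,
                          transverse_displacement)
    from .synthetic import generate_force_trace, generate_image_sequence

    cfg = config or StudyConfig()
    log: list[str] = [f"seed={cfg.seed}", f"participants={cfg.n_participants}",
                      f"stances={cfg.n_stances}"]
    master = np.random.default_rng(cfg.seed)

    input_rows = []
    spectra_rows = []
    for p in range(cfg.n_participants):
        p_rng = np.random.default_rng(master.integers(2**31))
        # --- generate all image sequences for this participant -------------
        sequences: dict[tuple[int, int], tuple] = {}
        for ci, cond in enumerate(cfg.conditions):
            n_frames = int(round(cond.stance_duration_s * cfg.frame_rate_hz))
            for st in range(cfg.n_stances):
                sup, deep = _scene_for(cond, p, st, p_rng)
                seq, scene = generate_image_sequence(
                    sup, deep, n_frames=n_frames,
                    frame_rate_hz=cfg.frame_rate_hz,
                    seed=int(p_rng.integers(2**31)),
                )
                sequences[(ci, st)] = (seq, scene)
        log.append(f"participant {p}: generated "
                   f"{len(sequences)} stance sequences")

        # --- per-participant ASM training (one model per aponeurosis) ------
        models = {}
        for apo in cfg.aponeuroses:
            train_pairs = []
            for ci in cfg.training_conditions:
                for st in range(cfg.n_stances):
                    seq, scene = sequences[(ci, st)]
                    labels = [
                        LandmarkShape.from_rows(scene.landmark_truth[apo][f], f)
                        for f in range(0, seq.n_frames, cfg.train_label_stride)
                    ]
                    train_pairs.append((seq, labels))
            models[apo] = train_shape_model(
                train_pairs, metadata={"participant": p, "aponeurosis": apo})
        log.append(f"participant {p}: trained models "
                   f"({', '.join(cfg.aponeuroses)})")

        # --- kinetics -------------------------------------------------------
        for ci, cond in enumerate(cfg.conditions):
            trace = generate_force_trace(
                gait=cond.gait, stance_duration_s=cond.stance_duration_s,
                impact_frequency_hz=cond.impact_frequency_hz,
                n_stances=cfg.n_stances, seed=int(p_rng.integers(2**31)),
            )
            table = analyze_force_trace(trace, prefiltered=True, threshold_N=5.0)
            for _, row in table.iterrows():
                input_rows.append({
                    "participant": p, "condition": cond.label,
                    "stance": int(row["stance_index"]),
                    "input_frequency_hz": row["input_frequency_hz"],
                })

        # --- segmentation + spectra ----------------------------------------
        for ci, cond in enumerate(cfg.conditions):
            for st in range(cfg.n_stances):
                seq, scene = sequences[(ci, st)]
                for apo in cfg.aponeuroses:
                    init = LandmarkShape.from_rows(
                        scene.landmark_truth[apo][0], 0)
                    traj = segment_sequence(models[apo], seq, init=init)
                    standing = LandmarkShape.from_rows(
                        scene.standing_rows(apo))
                    displ = transverse_displacement(
                        traj, standing, seq.mm_per_px_y,
                        condition=cond.label,
                        stride_frequency_hz=cond.stride_frequency_hz,
                    )
                    summaries = summarize_displacement(displ)
                    lookup = {i: name for name, idxs in REGIONS.items()
                              for i in idxs}
                    for s in summaries:
                        spectra_rows.append({
                            "participant": p, "condition": cond.label,
                            "stance": st, "aponeurosis": apo,
                            "landmark": s.landmark_index,
                            "region": lookup.get(s.landmark_index, "none"),
                            "peak_power_mm2": s.peak_power_mm2,
                            "cumulative_frequency_hz":
                                s.cumulative_frequency_hz,
                        })
        log.append(f"participant {p}: segmentation and spectra complete")

    input_df = pd.DataFrame(input_rows)
    spectra_df = pd.DataFrame(spectra_rows)

    cond_labels = [c.label for c in cfg.conditions]
    # --- statistics ---------------------------------------------------------
    anova_input = None
    anova_metrics: dict[tuple[str, str], RmAnovaResult] = {}
    trend_rows = []
    if cfg.n_participants >= 2 and len(cfg.conditions) >= 2:
        pivot = (input_df.groupby(["participant", "condition"], sort=False)
                 ["input_frequency_hz"].mean().unstack()[cond_labels])
        anova_input = rm_anova_one_way(pivot.to_numpy())
        if anova_input.effect("condition").p < 0.05:
            anova_input.posthoc = bonferroni_posthoc(pivot.to_numpy(),
                                                     cond_labels)
        region_names = list(REGIONS)
        for apo in cfg.aponeuroses:
            sub = spectra_df[(spectra_df.aponeurosis == apo)
                             & (spectra_df.region != "none")]
            for metric in ("peak_power_mm2", "cumulative_frequency_hz"):
                cube = np.empty((cfg.n_participants, len(region_names),
                                 len(cond_labels)))
                g = sub.groupby(["participant", "region", "condition"],
                                sort=False)[metric].mean()
                for pi in range(cfg.n_participants):
                    for ri, reg in enumerate(region_names):
                        for ki, lab in enumerate(cond_labels):
                            cube[pi, ri, ki] = g.loc[(pi, reg, lab)]
                anova_metrics[(apo, metric)] = rm_anova_two_way(cube)

        freq_means = (input_df.groupby("condition", sort=False)
                      ["input_frequency_hz"].mean()[cond_labels].to_numpy())
        for apo in cfg.aponeuroses:
            sub = spectra_df[spectra_df.aponeurosis == apo]
            for metric in ("peak_power_mm2", "cumulative_frequency_hz"):
                y = (sub.groupby("condition", sort=False)[metric]
                     .mean()[cond_labels].to_numpy())
                for deg in (1, 2):
                    fit = fit_trend(freq_means, y, deg)
                    trend_rows.append({
                        "aponeurosis": apo, "metric": metric, "degree": deg,
                        "r_squared": fit.r_squared,
                        **{f"c{i}": c for i, c in
                           enumerate(fit.coefficients)},
                    })
    else:
        log.append("ANOVA skipped: design has a single participant or "
                   "condition; metrics reported without inference")

    report = StudyReport(input_df, spectra_df, anova_input, anova_metrics,
                         pd.DataFrame(trend_rows), log)
    if out_dir is not None:
        report.write(out_dir)
    return report
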