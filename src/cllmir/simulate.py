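"""Synthetic miRNA profiling cohort generator.

Emulates the design of a bead-array miRNA profiling study of chronic
lymphocytic leukemia (CLL): 38 CLL samples, 9 resting control B-cell
samples and 5 CpG-activated B-cell samples measured on a ~50-miRNA
panel, with

* log2-normal bead intensities — log2 intensity = baseline + group
  effect + N(0, noise_sd^2), raw intensity = 2**log2;
* planted activation-signature effects (up in both CLL and activated B
  relative to control, down likewise), with configurable magnitudes up
  to ~50-fold up (miR-155) and ~100-fold down (miR-181a/b);
* one high-background feature (an additive raw-scale offset on all
  samples) to exercise the downstream exclusion path, mirroring
  miR-146b-5p on the real platform;
* clinical covariates (ZAP70, IgVH mutation status) assigned by
  thresholding a latent prognostic score so association tests have
  planted signal (defaults 14/38 positive each);
* censored time-to-first-therapy outcomes from an exponential
  proportional-hazards model whose log-hazard is linear in the
  standardized expression of two designated prognostic miRNAs
  (negative coefficient => low expression, shorter time);
* replicate RT-PCR Ct tables in which the target-minus-reference Ct
  drops one cycle per two-fold planted abundance increase.

Every simulated cohort carries a :class:`GroundTruth` record so
downstream recovery tests can compare what the analysis finds against
what was planted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .signature import ACTIVATION_DOWN, ACTIVATION_UP
from . import io

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "ConfigError",
    "default_feature_names",
    "generate_cohort",
    "generate_survival",
    "generate_ct_table",
]


class ConfigError(ValueError):
    """A cohort configuration field is invalid; the message names it."""


#: Panel filler: miRNAs profiled on the platform beyond the signature,
#: used to pad the default feature list to a realistic panel size.
_PANEL_EXTRA = (
    "let-7g", "miR-23a", "miR-23b", "miR-24", "miR-26a", "miR-27b",
    "miR-29a", "miR-29b", "miR-29c", "miR-92a", "miR-101", "miR-150",
    "miR-223", "miR-146b-5p", "miR-16", "miR-15a", "miR-21", "miR-30b",
    "miR-30c", "miR-106a", "miR-125b", "miR-142-3p", "miR-142-5p",
    "miR-191", "miR-222", "miR-320", "miR-361", "miR-422a", "miR-425",
    "miR-451", "miR-484", "miR-486", "miR-494", "miR-564", "miR-574",
    "miR-594", "miR-598", "miR-629",
)


def default_feature_names() -> list:
    """The default 50-miRNA panel (signature members + panel filler)."""
    names = list(ACTIVATION_UP) + list(ACTIVATION_DOWN) + list(_PANEL_EXTRA)
    assert len(names) == len(set(names)) == 50
    return names


def _default_planted_up() -> dict:
    # miR-155 rises ~50-fold in CLL; other up-members a uniform 2 log2 units
    eff = {m: 2.0 for m in ACTIVATION_UP}
    eff["miR-155"] = math.log2(50.0)
    return eff


def _default_planted_down() -> dict:
    # miR-181a/b fall ~100-fold; other down-members a uniform 2 log2 units
    eff = {m: -2.0 for m in ACTIVATION_DOWN}
    eff["miR-181a"] = -math.log2(100.0)
    eff["miR-181b"] = -math.log2(100.0)
    return eff


@dataclass
class CohortConfig:
    """Parameters of a simulated profiling cohort.

    ``planted_up`` / ``planted_down`` map feature ids to signed log2
    effects applied to the CLL and activated groups relative to control.
    ``prognostic_features`` maps exactly two feature ids to hazard
    coefficients for the survival generator.
    """

    n_cll: int = 38
    n_control: int = 9
    n_activated: int = 5
    feature_names: Sequence[str] = field(default_factory=default_feature_names)
    planted_up: Mapping[str, float] = field(default_factory=_default_planted_up)
    planted_down: Mapping[str, float] = field(default_factory=_default_planted_down)
    noise_sd_log2: float = 0.5
    baseline_log2_mean: float = 8.0
    high_background_features: frozenset = frozenset({"miR-146b-5p"})
    high_background_offset: float | None = None  # raw scale; None => 10x baseline
    prognostic_features: Mapping[str, float] = field(
        default_factory=lambda: {"miR-29c": -1.0, "miR-223": -1.0}
    )
    # the prognostic miRNAs co-vary (they track one latent disease-
    # aggressiveness axis); pairwise correlation of their noise terms
    prognostic_correlation: float = 0.7
    baseline_ttft_days: float = 1500.0
    censor_rate: float = 0.3
    frac_zap70_pos: float = 14 / 38
    frac_igvh_unmutated: float = 14 / 38
    seed: int = 0

    def __post_init__(self):
        if self.n_cll < 2:
            raise ConfigError("n_cll must be >= 2 (group statistics need >=2)")
        if self.n_control < 2:
            raise ConfigError("n_control must be >= 2 (group statistics need >=2)")
        if self.n_activated < 0:
            raise ConfigError("n_activated must be >= 0")
        names = list(self.feature_names)
        if len(names) != len(set(names)):
            raise ConfigError("feature_names contains duplicates")
        if not names:
            raise ConfigError("feature_names is empty")
        self.feature_names = names
        self.planted_up = dict(self.planted_up)
        self.planted_down = dict(self.planted_down)
        overlap = set(self.planted_up) & set(self.planted_down)
        if overlap:
            raise ConfigError(
                f"planted_up and planted_down overlap: {sorted(overlap)}"
            )
        known = set(names)
        for fld in ("planted_up", "planted_down", "prognostic_features"):
            extra = set(getattr(self, fld)) - known
            if extra:
                raise ConfigError(
                    f"{fld} references unknown features: {sorted(extra)}"
                )
        bad_dir = [m for m, e in self.planted_up.items() if e < 0]
        bad_dir += [m for m, e in self.planted_down.items() if e > 0]
        if bad_dir:
            raise ConfigError(
                f"planted effect signs inconsistent with direction: {bad_dir}"
            )
        if not self.noise_sd_log2 > 0:
            raise ConfigError("noise_sd_log2 must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError("censor_rate must be in [0, 1]")
        for fld in ("frac_zap70_pos", "frac_igvh_unmutated"):
            if not 0.0 <= getattr(self, fld) <= 1.0:
                raise ConfigError(f"{fld} must be in [0, 1]")
        if not all(np.isfinite(list(self.prognostic_features.values()) or [0.0])):
            raise ConfigError("prognostic_features coefficients must be finite")
        if not 0.0 <= self.prognostic_correlation < 1.0:
            raise ConfigError("prognostic_correlation must be in [0, 1)")
        if self.baseline_ttft_days <= 0:
            raise ConfigError("baseline_ttft_days must be > 0")

    @property
    def sample_ids(self) -> list:
        return (
            [f"L{i + 1:02d}" for i in range(self.n_cll)]
            + [f"CB{i + 1}" for i in range(self.n_control)]
            + [f"CB{i + 1}act" for i in range(self.n_activated)]
        )

    @property
    def groups(self) -> list:
        return (
            ["CLL"] * self.n_cll
            + ["control_B"] * self.n_control
            + ["activated_B"] * self.n_activated
        )


@dataclass
class GroundTruth:
    """What was planted in a simulated cohort.

    ``latent_log2`` holds the noiseless per-sample log2 abundances
    (baseline + group effect), i.e. the group means broadcast over
    samples; it is what the Ct generator and recovery tests consume.
    """

    true_up: dict
    true_down: dict
    group_means_log2: pd.DataFrame  # features x groups
    latent_log2: pd.DataFrame       # features x samples, noiseless
    prognostic_features: dict
    true_cutpoints: dict = field(default_factory=dict)
    high_background_features: list = field(default_factory=list)

    def to_json(self, path) -> None:
        io.write_json(
            {
                "true_up": self.true_up,
                "true_down": self.true_down,
                "group_means_log2": self.group_means_log2.to_dict(orient="split"),
                "latent_log2": self.latent_log2.to_dict(orient="split"),
                "prognostic_features": self.prognostic_features,
                "true_cutpoints": self.true_cutpoints,
                "high_background_features": list(self.high_background_features),
            },
            path,
        )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = io.read_json(path)

        def _frame(split):
            return pd.DataFrame(
                split["data"], index=split["index"], columns=split["columns"]
            )

        return cls(
            true_up=d["true_up"],
            true_down=d["true_down"],
            group_means_log2=_frame(d["group_means_log2"]),
            latent_log2=_frame(d["latent_log2"]),
            prognostic_features=d["prognostic_features"],
            true_cutpoints=d["true_cutpoints"],
            high_background_features=d["high_background_features"],
        )


def _effect(config: CohortConfig, feature: str) -> float:
    return config.planted_up.get(feature, 0.0) + config.planted_down.get(feature, 0.0)


def generate_cohort(config: CohortConfig):
    """Simulate a raw-intensity cohort.

    Returns
    -------
    matrix : DataFrame, features x samples
        Raw bead intensities (positive reals), i.e. ``2**log2`` of the
        latent abundances plus noise, plus the additive high-background
        offset where configured.
    table : DataFrame indexed by sample_id
        Columns ``group, zap70, igvh, ttft_days, event`` (survival
        fields NaN until :func:`generate_survival` fills them).
    truth : GroundTruth
    """
    rng = np.random.default_rng(config.seed)
    features = list(config.feature_names)
    samples = config.sample_ids
    groups = config.groups

    group_means = pd.DataFrame(
        config.baseline_log2_mean,
        index=features,
        columns=list(io.GROUPS),
        dtype=float,
    )
    for f in features:
        eff = _effect(config, f)
        # planted effects act in CLL and activated B relative to control
        group_means.loc[f, "CLL"] += eff
        group_means.loc[f, "activated_B"] += eff

    latent = pd.DataFrame(
        {s: group_means[g] for s, g in zip(samples, groups)},
        index=features,
    )
    noise = rng.normal(0.0, config.noise_sd_log2, size=latent.shape)
    # prognostic miRNAs share a latent per-sample aggressiveness factor,
    # keeping each feature's marginal SD at noise_sd_log2 while giving the
    # pair a correlation of prognostic_correlation
    prog = [f for f in config.prognostic_features if f in latent.index]
    if len(prog) >= 2 and config.prognostic_correlation > 0:
        rho = config.prognostic_correlation
        shared = rng.normal(0.0, 1.0, size=latent.shape[1])
        for f in prog:
            i = latent.index.get_loc(f)
            own = rng.normal(0.0, 1.0, size=latent.shape[1])
            noise[i] = config.noise_sd_log2 * (
                np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            )
    log2_matrix = latent + noise
    raw = np.power(2.0, log2_matrix)

    offset = config.high_background_offset
    if offset is None:
        offset = 10.0 * 2.0 ** config.baseline_log2_mean
    for f in config.high_background_features:
        if f in raw.index:
            raw.loc[f] = raw.loc[f] + offset

    table = pd.DataFrame(
        {
            "group": groups,
            "zap70": "NA",
            "igvh": "NA",
            "ttft_days": np.nan,
            "event": np.nan,
        },
        index=pd.Index(samples, name="sample_id"),
    )

    # Latent prognostic score: standardized realized expression of the
    # prognostic features summed with their hazard coefficients' signs
    # flipped, so a HIGH score means poor prognosis. ZAP70+/IgVH-unmutated
    # are the worst-score patients (counts set by the configured fractions).
    cll_ids = [s for s, g in zip(samples, groups) if g == "CLL"]
    score = pd.Series(0.0, index=cll_ids)
    for f, coef in config.prognostic_features.items():
        expr = log2_matrix.loc[f, cll_ids]
        sd = expr.std(ddof=1)
        z = (expr - expr.mean()) / (sd if sd > 0 else 1.0)
        score += np.sign(coef) * -z if coef != 0 else 0.0
    n_pos = int(round(config.frac_zap70_pos * len(cll_ids)))
    n_unmut = int(round(config.frac_igvh_unmutated * len(cll_ids)))
    order = score.sort_values(ascending=False, kind="mergesort").index
    table.loc[cll_ids, "zap70"] = "neg"
    table.loc[order[:n_pos], "zap70"] = "pos"
    table.loc[cll_ids, "igvh"] = "mutated"
    table.loc[order[:n_unmut], "igvh"] = "unmutated"

    truth = GroundTruth(
        true_up={m: e for m, e in config.planted_up.items()},
        true_down={m: e for m, e in config.planted_down.items()},
        group_means_log2=group_means,
        latent_log2=latent,
        prognostic_features=dict(config.prognostic_features),
        high_background_features=sorted(
            set(config.high_background_features) & set(features)
        ),
    )
    return raw, table, truth


def _uniform_censor_max(rate_target: float, hazards: np.ndarray) -> float:
    """Admin horizon m such that exponential times (per-subject rates
    ``hazards``) censored by U(0, m) are censored with probability
    ``rate_target`` on average over subjects."""
    # P(C < T | hazard h) = (1 - exp(-h*m)) / (h*m), decreasing in m
    def f(m):
        x = hazards * m
        return float(np.mean(-np.expm1(-x) / x)) - rate_target

    lo, hi = 1e-9, 1e15
    return brentq(f, lo, hi, maxiter=200)


def generate_survival(
    config: CohortConfig,
    truth: GroundTruth,
    table: pd.DataFrame,
    matrix: pd.DataFrame,
) -> pd.DataFrame:
    """Fill time-to-first-therapy outcomes for the CLL samples.

    Event times are exponential with log-hazard linear in the
    standardized log2 expression of the prognostic features; censoring
    times are uniform on [0, m] with m solved so the expected censoring
    fraction matches ``config.censor_rate``. Non-CLL samples keep
    missing survival fields. Also records the median-expression
    cut-point of each prognostic feature in ``truth.true_cutpoints``.
    """
    missing = [f for f in config.prognostic_features if f not in matrix.index]
    if missing:
        raise KeyError(f"prognostic features absent from matrix: {missing}")

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    )
    table = table.copy()
    cll_ids = table.index[table["group"] == "CLL"]
    log2_expr = np.log2(np.maximum(matrix.loc[:, cll_ids], 1.0))

    lp = pd.Series(0.0, index=cll_ids)
    for f, coef in config.prognostic_features.items():
        vals = log2_expr.loc[f]
        sd = vals.std(ddof=1)
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        lp += coef * z
        truth.true_cutpoints[f] = float(vals.median())

    base_hazard = 1.0 / config.baseline_ttft_days
    hazards = base_hazard * np.exp(lp.to_numpy())
    times = rng.exponential(1.0 / hazards)

    if config.censor_rate <= 0.0:
        obs, event = times, np.ones(len(times), dtype=int)
    elif config.censor_rate >= 1.0:
        obs = rng.uniform(0.0, config.baseline_ttft_days, size=len(times))
        event = np.zeros(len(times), dtype=int)
    else:
        m = _uniform_censor_max(config.censor_rate, hazards)
        cens = rng.uniform(0.0, m, size=len(times))
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)

    table.loc[cll_ids, "ttft_days"] = np.maximum(obs, 1e-6)
    table.loc[cll_ids, "event"] = event
    return table


def generate_ct_table(
    config: CohortConfig,
    truth: GroundTruth,
    reference: str = "RNU44",
    targets: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
    n_replicates: int = 3,
    replicate_sd: float = 0.25,
    target_ct_at_baseline: float = 30.0,
    reference_ct: float = 25.0,
) -> pd.DataFrame:
    """Simulate an RT-PCR Ct table normalized by a small-RNA reference.

    By construction Ct(target) = target_ct_at_baseline - (latent log2
    abundance - baseline) + noise and Ct(reference) is constant across
    samples, so the sample's delta-Ct decreases one cycle per planted
    two-fold abundance increase. Every sample receives reference rows.
    """
    if not reference:
        raise ValueError("a reference (normalizer) target must be designated")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    if replicate_sd < 0:
        raise ConfigError("replicate_sd must be >= 0")

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(2,))
    )
    if targets is None:
        targets = sorted(set(truth.true_up) | set(truth.true_down))
    if samples is None:
        samples = [
            s
            for s, g in zip(config.sample_ids, config.groups)
            if g in ("CLL", "control_B")
        ]
    unknown = [t for t in targets if t not in truth.latent_log2.index]
    if unknown:
        raise ConfigError(f"Ct targets absent from ground truth: {unknown}")

    rows = []
    for s in samples:
        for rep in range(1, n_replicates + 1):
            ct_ref = reference_ct + rng.normal(0.0, replicate_sd)
            rows.append((s, reference, rep, float(np.clip(ct_ref, 1.0, 49.0))))
        for t in targets:
            latent = truth.latent_log2.loc[t, s]
            center = target_ct_at_baseline - (latent - config.baseline_log2_mean)
            for rep in range(1, n_replicates + 1):
                ct = center + rng.normal(0.0, replicate_sd)
                rows.append((s, t, rep, float(np.clip(ct, 1.0, 49.0))))
    return pd.DataFrame(rows, columns=["sample_id", "target", "replicate", "ct"])


def write_cohort(outdir, matrix, table, truth) -> dict:
    """Write a simulated cohort to disk; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    paths = {
        "matrix": outdir / "expression_raw.tsv",
        "samples": outdir / "samples.csv",
        "truth": outdir / "ground_truth.json",
    }
    io.write_matrix(matrix, paths["matrix"])
    io.write_sample_table(table, paths["samples"])
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
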