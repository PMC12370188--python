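"""Counterbalanced 2-IFC sessions, simulated observers, exclusion,
reliability, and trial-level model-human correspondence.

The behavioral paradigm is a two-interval forced choice: on each trial the
observer sees the contour-present and contour-absent member of one matched
pair (order counterbalanced) and reports which interval contained the
contour. Sessions hold 200 trials from one behavioral split, organized as
5 blocks x 2 mini-blocks x 20 trials with every (curvature, interval)
condition appearing exactly twice per mini-block.

Human observers are emulated by a simulated-observer model: per-condition
accuracy follows a 2-IFC Weibull psychometric function of the curvature
beta,

    P(correct | beta) = 0.5 + (0.5 - lapse) * exp(-(beta/threshold)^slope),

perturbed on the logit scale by a per-pair difficulty offset shared across
participants, which produces the reliable trial-level variation the
analysis pipeline is built to measure.

Model decision strength for a pair is the contour signal

    s = (response_present - response_absent) / 2,

half the difference of the contour-present node's responses to the two
images (equivalently, scaled perpendicular distance from the identity line
of the present-vs-absent response scatter). The pipeline correlates s with
per-trial percent correct and reports it against the Spearman-Brown
corrected split-half reliability of the behavioral data (the noise
ceiling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ObserverParams",
    "WeibullFit",
    "CorrespondenceReport",
    "build_session",
    "weibull_p",
    "make_trial_difficulties",
    "simulate_observers",
    "fit_psychometric",
    "exclude_participants",
    "ExclusionAborted",
    "trial_accuracy",
    "spearman_brown",
    "split_half_reliability",
    "predicted_split_half_r",
    "contour_signal",
    "fisher_ci",
    "model_human_correlation",
]


# ---------------------------------------------------------------------------
# sessions
# ---------------------------------------------------------------------------

def build_session(split_df: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Order one behavioral split (200 pairs, 40 per curvature) into a
    counterbalanced session.

    Each (beta, present-interval) condition gets 20 trials; every mini-block
    of 20 trials holds exactly 2 trials of each of the 10 conditions, with
    order randomized within mini-blocks only. Returns one row per trial:
    trial_index, pair_id, beta_deg, present_interval, rotation_1,
    rotation_2, block, miniblock.
    """
    betas = np.sort(split_df["beta_deg"].unique())
    if len(split_df) != 200 or len(betas) != 5:
        raise ValueError("split must contain 200 pairs over 5 curvatures")
    if split_df["pair_id"].nunique() != 200:
        raise ValueError("duplicate pair ids in split")
    rng = np.random.default_rng(seed)

    assignments: dict[tuple[float, int], list[dict]] = {}
    for beta in betas:
        sub = split_df[split_df["beta_deg"] == beta]
        if len(sub) != 40:
            raise ValueError("each curvature needs 40 pairs")
        rows = sub.sample(frac=1.0, random_state=rng.integers(2 ** 31)) \
                  .to_dict("records")
        assignments[(beta, 1)] = rows[:20]
        assignments[(beta, 2)] = rows[20:]

    minis: list[list[dict]] = [[] for _ in range(10)]
    for cond, rows in assignments.items():
        rng.shuffle(rows)
        for m in range(10):
            for r in rows[2 * m:2 * m + 2]:
                minis[m].append({**r, "present_interval": cond[1]})
    trials = []
    for m, bucket in enumerate(minis):
        rng.shuffle(bucket)
        for t in bucket:
            trials.append({
                "pair_id": t["pair_id"], "beta_deg": t["beta_deg"],
                "present_interval": t["present_interval"],
                "rotation_1": t.get("rotation_1", 0),
                "rotation_2": t.get("rotation_2", 90),
                "block": m // 2, "miniblock": m,
            })
    out = pd.DataFrame(trials)
    out.insert(0, "trial_index", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# simulated observers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverParams:
    weibull_threshold: float = 45.0
    weibull_slope: float = 2.0
    lapse_rate: float = 0.02
    guess_rate: float = 0.5
    trial_difficulty_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must be in [0, 0.1]")


def weibull_p(beta, threshold: float, slope: float, lapse: float,
              guess: float = 0.5):
    """2-IFC Weibull: accuracy decays from (1 - lapse) toward the guessing
    floor as curvature grows past the threshold."""
    beta = np.asarray(beta, dtype=float)
    return guess + (1.0 - guess - lapse) * np.exp(-(beta / threshold) ** slope)


def _logit(p):
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def make_trial_difficulties(pair_ids, sd: float,
                            rng: np.random.Generator) -> pd.Series:
    """Shared per-pair difficulty offsets (logit units), fixed across
    participants."""
    ids = pd.Index(pd.unique(pd.Series(pair_ids)))
    return pd.Series(rng.normal(0.0, sd, size=len(ids)), index=ids)


def simulate_observers(params_list, sessions: dict[int, pd.DataFrame],
                       difficulties: pd.Series,
                       splits_of: dict[int, int] | None = None
                       ) -> pd.DataFrame:
    """Per-trial binary responses for a cohort.

    ``sessions`` maps participant id -> session table; each participant's
    per-trial probability is the Weibull value for the trial's curvature,
    shifted on the logit scale by the pair's shared difficulty offset.
    Returns one row per (participant, trial) with the realized correctness.
    """
    rows = []
    clip_count = 0
    for pid, params in enumerate(params_list):
        session = sessions[pid]
        rng = np.random.default_rng(params.seed)
        base = weibull_p(session["beta_deg"].to_numpy(),
                         params.weibull_threshold, params.weibull_slope,
                         params.lapse_rate, params.guess_rate)
        offs = difficulties.reindex(session["pair_id"]).to_numpy()
        p = _sigmoid(_logit(base) + offs)
        bad = ~np.isfinite(p) | (p < 0) | (p > 1)
        if bad.any():
            clip_count += int(bad.sum())
            p = np.clip(np.nan_to_num(p, nan=0.5), 0.0, 1.0)
        correct = (rng.random(len(p)) < p).astype(int)
        frame = session[["trial_index", "pair_id", "beta_deg"]].copy()
        frame["participant"] = pid
        frame["split"] = splits_of[pid] if splits_of else 0
        frame["p_correct"] = p
        frame["correct"] = correct
        rows.append(frame)
    out = pd.concat(rows, ignore_index=True)
    out.attrs["n_clipped"] = clip_count
    if clip_count:
        import warnings
        warnings.warn(f"{clip_count} trial probabilities clipped to [0, 1]")
    return out


# ---------------------------------------------------------------------------
# psychometric fitting
# ---------------------------------------------------------------------------

@dataclass
class WeibullFit:
    threshold: float
    slope: float
    lapse: float
    converged: bool
    flagged: bool = False


def fit_psychometric(betas, accuracies) -> WeibullFit:
    """Least-squares fit of the 2-IFC Weibull (guess fixed at 0.5, lapse
    capped at 0.1). Fits pinned to the parameter bounds or with accuracy
    flat at floor/ceiling are flagged."""
    betas = np.asarray(betas, dtype=float)
    acc = np.asarray(accuracies, dtype=float)
    if len(betas) < 3:
        raise ValueError("need at least 3 curvature levels")

    def resid(theta):
        th, sl, la = theta
        return weibull_p(betas, th, sl, la) - acc

    lo = [1e-2, 0.1, 0.0]
    hi = [1e4, 20.0, 0.1]
    x0 = [max(np.median(betas), 1.0), 2.0, 0.01]
    res = least_squares(resid, x0, bounds=(lo, hi))
    th, sl, la = res.x
    flagged = (not res.success or th <= betas.min() * 0.5
               or th >= betas.max() * 10 or np.ptp(acc) < 0.05)
    return WeibullFit(threshold=float(th), slope=float(sl), lapse=float(la),
                      converged=bool(res.success), flagged=bool(flagged))


# ---------------------------------------------------------------------------
# exclusion
# ---------------------------------------------------------------------------

class ExclusionAborted(RuntimeError):
    def __init__(self, message: str, audit: pd.DataFrame):
        super().__init__(message)
        self.audit = audit


def exclude_participants(responses: pd.DataFrame
                         ) -> tuple[list[int], pd.DataFrame]:
    """Two-stage recursive outlier removal.

    Stage 1 removes, one at a time, the participant whose overall accuracy
    is farthest beyond 2.5 sample standard deviations from the remaining
    group's mean. Stage 2 computes each remaining participant's 5-dim
    per-curvature accuracy profile, correlates it with the leave-one-out
    group mean profile, and recursively removes correlations beyond 2.5 SD
    of the correlation distribution. Ties at exactly 2.5 SD are kept.
    Returns kept participant ids and an audit log (order, stage, value).
    """
    ids = sorted(responses["participant"].unique())
    if len(ids) < 3:
        raise ExclusionAborted("need at least 3 participants", pd.DataFrame())
    audit: list[dict] = []
    kept = list(ids)
    overall = responses.groupby("participant")["correct"].mean()
    profiles = (responses.groupby(["participant", "beta_deg"])["correct"]
                .mean().unstack())

    def stage1() -> bool:
        removed = False
        while True:
            vals = overall.loc[kept]
            mu, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0:
                return removed
            dev = (vals - mu).abs() / sd
            worst = dev.idxmax()
            if dev.loc[worst] <= 2.5:
                return removed
            kept.remove(worst)
            removed = True
            audit.append({"participant": worst, "stage": 1,
                          "reason": "overall_accuracy",
                          "value": float(vals.loc[worst]),
                          "z": float(dev.loc[worst])})
            if len(kept) < 3:
                raise ExclusionAborted("fewer than 3 survivors after stage 1",
                                       pd.DataFrame(audit))

    def stage2() -> bool:
        removed = False
        while True:
            prof = profiles.loc[kept]
            corrs = {}
            for pid in kept:
                others = prof.drop(index=pid).mean(axis=0)
                own = prof.loc[pid]
                if own.std(ddof=0) == 0 or others.std(ddof=0) == 0:
                    corrs[pid] = 0.0
                else:
                    corrs[pid] = float(np.corrcoef(own, others)[0, 1])
            cvals = pd.Series(corrs)
            mu, sd = cvals.mean(), cvals.std(ddof=1)
            if sd == 0:
                return removed
            dev = (cvals - mu).abs() / sd
            worst = dev.idxmax()
            if dev.loc[worst] <= 2.5:
                return removed
            kept.remove(worst)
            removed = True
            audit.append({"participant": worst, "stage": 2,
                          "reason": "beta_profile_correlation",
                          "value": float(cvals.loc[worst]),
                          "z": float(dev.loc[worst])})
            if len(kept) < 3:
                raise ExclusionAborted("fewer than 3 survivors after stage 2",
                                       pd.DataFrame(audit))

    # accuracy stage first, then profile stage; repeat to a joint fixed
    # point so the procedure is idempotent on its own output
    while True:
        changed = stage1()
        changed = stage2() or changed
        if not changed:
            break

    return kept, pd.DataFrame(audit, columns=["participant", "stage",
                                              "reason", "value", "z"])


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def trial_accuracy(responses: pd.DataFrame,
                   participants=None) -> pd.DataFrame:
    """Percent correct per pair across (kept) participants."""
    df = responses
    if participants is not None:
        df = df[df["participant"].isin(participants)]
    g = df.groupby("pair_id")["correct"].agg(["mean", "count"])
    return pd.DataFrame({"pair_id": g.index,
                         "percent_correct": 100.0 * g["mean"],
                         "n_responses": g["count"]}).reset_index(drop=True)


def spearman_brown(r: float) -> float:
    """Reliability of the doubled test: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(responses: pd.DataFrame, n_boot: int = 1000,
                           seed: int = 0, participants=None
                           ) -> tuple[float, float, tuple[float, float]]:
    """Split-half reliability of per-trial percent correct.

    Participants are randomly halved (stratified by behavioral split when a
    ``split`` column is present), per-trial percent correct is computed in
    each half over the trials both halves cover, and the halves are
    correlated; the Spearman-Brown correction estimates full-cohort
    reliability. Returns (mean raw r, mean corrected r, percentile 95% CI
    of the corrected values over the random re-splits).
    """
    df = responses
    if participants is not None:
        df = df[df["participant"].isin(participants)]
    ids = np.array(sorted(df["participant"].unique()))
    if len(ids) < 4:
        raise ValueError("need at least 4 participants")
    split_of = (df.groupby("participant")["split"].first()
                if "split" in df else pd.Series(0, index=ids))
    rng = np.random.default_rng(seed)
    by_pair = df.set_index("participant")
    raws, correcteds = [], []
    attempts = 0
    while len(raws) < n_boot and attempts < 4 * n_boot:
        attempts += 1
        half_a = []
        for s in np.unique(split_of.loc[ids]):
            members = ids[split_of.loc[ids].to_numpy() == s]
            perm = rng.permutation(members)
            half_a.extend(perm[:len(perm) // 2].tolist())
        mask_a = df["participant"].isin(half_a)
        pc_a = df[mask_a].groupby("pair_id")["correct"].mean()
        pc_b = df[~mask_a].groupby("pair_id")["correct"].mean()
        common = pc_a.index.intersection(pc_b.index)
        a, b = pc_a.loc[common], pc_b.loc[common]
        if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
            continue  # degenerate half: resample
        r = float(np.corrcoef(a, b)[0, 1])
        raws.append(r)
        correcteds.append(spearman_brown(r))
    correcteds = np.array(correcteds)
    ci = (float(np.percentile(correcteds, 2.5)),
          float(np.percentile(correcteds, 97.5)))
    return float(np.mean(raws)), float(np.mean(correcteds)), ci


def predicted_split_half_r(p_trials: np.ndarray, n_half: int) -> float:
    """Analytic attenuation prediction for the raw split-half correlation:
    with true per-trial probabilities p and n_half binomial responses per
    half, r = Var(p) / (Var(p) + E[p(1-p)]/n_half)."""
    p = np.asarray(p_trials, dtype=float)
    vp = p.var()
    noise = np.mean(p * (1 - p)) / n_half
    return float(vp / (vp + noise))


# ---------------------------------------------------------------------------
# model signal and correspondence
# ---------------------------------------------------------------------------

def contour_signal(response_present, response_absent):
    """Half the difference of the contour-present node's responses to the
    two members of a matched pair; antisymmetric under swapping them."""
    rp = np.asarray(response_present, dtype=float)
    ra = np.asarray(response_absent, dtype=float)
    if not (np.all(np.isfinite(rp)) and np.all(np.isfinite(ra))):
        raise ValueError("responses must be finite")
    return (rp - ra) / 2.0


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    z = math.atanh(max(min(r, 1 - 1e-12), -1 + 1e-12))
    se = 1.0 / math.sqrt(n - 3)
    crit = 1.959963984540054
    return math.tanh(z - crit * se), math.tanh(z + crit * se)


@dataclass
class CorrespondenceReport:
    pearson_r: float
    ci95_low: float
    ci95_high: float
    n_trials: int
    noise_ceiling: float | None = None
    noise_ceiling_ci: tuple[float, float] | None = None


def model_human_correlation(signal: pd.Series, accuracy: pd.Series,
                            noise_ceiling: float | None = None,
                            noise_ceiling_ci=None) -> CorrespondenceReport:
    """Pearson correlation between per-pair model contour signal and human
    percent correct, with a Fisher-z 95% CI, reported next to the
    reliability noise ceiling."""
    common = signal.index.intersection(accuracy.index)
    if len(common) < 3:
        raise ValueError("need at least 3 aligned trials")
    s = signal.loc[common].to_numpy(dtype=float)
    a = accuracy.loc[common].to_numpy(dtype=float)
    r = float(np.corrcoef(s, a)[0, 1])
    lo, hi = fisher_ci(r, len(common))
    return CorrespondenceReport(pearson_r=r, ci95_low=lo, ci95_high=hi,
                                n_trials=len(common),
                                noise_ceiling=noise_ceiling,
                                noise_ceiling_ci=noise_ceiling_ci)
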