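"""Model-vs-expert evaluation statistics.

ROC AUC via the rank (Mann–Whitney) formulation with mid-ranks for ties;
the paired DeLong test for comparing two correlated AUCs measured on the
same videos (structural-components variance estimator, two-sided normal
reference); survey-response analytics (per-participant accuracy over
answered videos, vote-fraction pooling into a per-video expert score);
accuracy correlations; and a dog-stratified permutation test that stands
in for mixed-model fits of area effects on kinematic features: the
statistic is the difference of dog-mean feature values between the target
and a comparison area averaged over dogs, with the null built by permuting
area labels within dog × session strata (so dog identity and session-level
drift can never masquerade as an odour effect).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

RESPONSE_TARGET = "target_present"
RESPONSE_ABSENT = "target_absent"
RESPONSE_SKIP = "skipped"

DEMOGRAPHIC_COLUMNS = ("participant_id", "age", "experience_category",
                       "paid_experience_years", "continent")


# ---------------------------------------------------------------------------
# AUC and the DeLong test
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """AUC by mid-rank Mann–Whitney; ties contribute 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    y = _binary(y)
    m = int(y.sum())
    n = y.size - m
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(s)  # mid-ranks
    return float((r[y == 1].sum() - m * (m + 1) / 2.0) / (m * n))


def _binary(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":
        return np.array([1 if str(v) == "target" else 0 for v in arr])
    return arr.astype(int)


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong V10 (per positive) and V01 (per negative) via mid-ranks."""
    pos, neg = scores[y == 1], scores[y == 0]
    m, n = pos.size, neg.size
    r_all = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov: float
    z: float
    p: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("auc_a", "auc_b", "var_a", "var_b", "cov", "z", "p", "degenerate")}


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single AUC estimate."""
    y = _binary(labels)
    v10, v01 = _structural_components(np.asarray(scores, dtype=float), y)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_paired_test(scores_a, scores_b, labels) -> DeLongResult:
    """Paired DeLong test for two correlated AUCs on the same videos.

    z = (AUC_a - AUC_b)/sqrt(var_a + var_b - 2 cov); two-sided p from the
    normal reference.  When the variance of the difference degenerates
    (e.g. identical score vectors) p is reported as NaN with the
    ``degenerate`` flag set — except for the exact-identity case, which is
    reported as z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = _binary(labels)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must align")
    auc_a, auc_b = roc_auc(a, y), roc_auc(b, y)
    va10, va01 = _structural_components(a, y)
    vb10, vb01 = _structural_components(b, y)
    m, n = va10.size, va01.size
    s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    cov_mat = s10 / m + s01 / n
    var_a, var_b, cov = float(cov_mat[0, 0]), float(cov_mat[1, 1]), float(cov_mat[0, 1])
    var_diff = var_a + var_b - 2 * cov
    if np.allclose(a, b):
        return DeLongResult(auc_a, auc_b, var_a, var_b, cov, 0.0, 1.0)
    if var_diff <= 0:
        return DeLongResult(auc_a, auc_b, var_a, var_b, cov, float("nan"), float("nan"), degenerate=True)
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, var_a, var_b, cov, float(z), float(p))


# ---------------------------------------------------------------------------
# expert survey analytics
# ---------------------------------------------------------------------------

@dataclass
class ExpertResponseTable:
    """One row per participant: demographics + one response column per
    video id, values in {target_present, target_absent, skipped}."""

    table: pd.DataFrame
    video_ids: list[str]

    def __post_init__(self):
        missing = set(self.video_ids) - set(self.table.columns)
        if missing:
            raise ValueError(f"response table lacks video columns: {sorted(missing)[:5]}")


def read_survey_table(path, video_ids: list[str] | None = None) -> ExpertResponseTable:
    df = pd.read_csv(path)
    if video_ids is None:
        video_ids = [c for c in df.columns if c not in DEMOGRAPHIC_COLUMNS]
    return ExpertResponseTable(table=df, video_ids=list(video_ids))


def expert_accuracy(table: ExpertResponseTable, truth: dict[str, str]) -> dict:
    """Per-participant and pooled accuracy over *answered* videos only,
    with paid-experience strata.  Participants answering nothing are
    excluded (noted)."""
    rows, excluded = [], []
    for _, r in table.table.iterrows():
        answered = correct = 0
        for vid in table.video_ids:
            resp = r[vid]
            if not isinstance(resp, str) or resp == RESPONSE_SKIP:
                continue
            answered += 1
            said_target = resp == RESPONSE_TARGET
            if said_target == (truth[vid] == "target"):
                correct += 1
        if answered == 0:
            excluded.append(r["participant_id"])
            continue
        paid = float(r.get("paid_experience_years", 0) or 0) > 0
        rows.append({"participant_id": r["participant_id"], "accuracy": correct / answered,
                     "n_answered": answered, "paid": paid})
    per = pd.DataFrame(rows)
    if per.empty:
        raise ValueError("no participant answered any video")
    out = {
        "per_participant": per,
        "pooled_accuracy": float(per["accuracy"].mean()),
        "paid_accuracy": float(per.loc[per["paid"], "accuracy"].mean()) if per["paid"].any() else float("nan"),
        "unpaid_accuracy": float(per.loc[~per["paid"], "accuracy"].mean()) if (~per["paid"]).any() else float("nan"),
        "n_excluded": len(excluded),
    }
    if excluded:
        log.info("excluded %d participants with zero answers", len(excluded))
    return out


def expert_video_scores(table: ExpertResponseTable) -> pd.DataFrame:
    """Pool participants into a per-video expert score: the fraction of
    responding participants answering target_present."""
    rows = []
    for vid in table.video_ids:
        col = table.table[vid]
        answered = col.isin([RESPONSE_TARGET, RESPONSE_ABSENT])
        n = int(answered.sum())
        score = float((col[answered] == RESPONSE_TARGET).mean()) if n else float("nan")
        rows.append({"video_id": vid, "expert_score": score, "n_responses": n})
    return pd.DataFrame(rows)


@dataclass
class ScoredVideoSet:
    """Aligned per-video truth, model score and pooled expert score."""

    video_id: list[str]
    true_label: np.ndarray      # 1 = target
    model_score: np.ndarray
    expert_score: np.ndarray
    n_responses: np.ndarray = field(default=None)

    def __post_init__(self):
        self.true_label = _binary(self.true_label)
        for s in (self.model_score, self.expert_score):
            if np.any((np.asarray(s) < 0) | (np.asarray(s) > 1)):
                raise ValueError("scores must lie in [0, 1]")

    def compare(self) -> DeLongResult:
        return delong_paired_test(self.model_score, self.expert_score, self.true_label)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _correlate(x, y, method: str):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 aligned observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def per_dog_accuracy_correlation(
    model_per_dog: dict[str, float],
    expert_per_dog: dict[str, float],
    method: str = "pearson",
) -> float:
    """Correlation of per-dog mean accuracies, model vs experts (are the
    same dogs hard for both?)."""
    dogs = sorted(set(model_per_dog) & set(expert_per_dog))
    if len(dogs) < 3:
        raise ValueError("need >= 3 dogs in common")
    return _correlate([model_per_dog[d] for d in dogs], [expert_per_dog[d] for d in dogs], method)


def expert_per_dog_accuracy(
    table: ExpertResponseTable, truth: dict[str, str], video_to_dog: dict[str, str]
) -> dict[str, float]:
    """Mean expert correctness per dog (pooled over participants/videos)."""
    acc: dict[str, list] = {}
    for vid in table.video_ids:
        col = table.table[vid]
        answered = col.isin([RESPONSE_TARGET, RESPONSE_ABSENT])
        if not answered.any():
            continue
        correct = (col[answered] == RESPONSE_TARGET) == (truth[vid] == "target")
        acc.setdefault(video_to_dog[vid], []).extend(correct.tolist())
    return {d: float(np.mean(v)) for d, v in acc.items()}


def length_accuracy_correlation(video_lengths, per_video_accuracy, method: str = "pearson") -> float:
    """Correlation of clip duration with mean per-video correctness."""
    return _correlate(video_lengths, per_video_accuracy, method)


# ---------------------------------------------------------------------------
# dog-stratified permutation test
# ---------------------------------------------------------------------------

def area_effect_permutation(
    feature_df: pd.DataFrame,
    feature: str,
    n_perm: int = 999,
    seed: int = 0,
    target: str = "target",
    comparison: str = "no_odour",
) -> tuple[float, float]:
    """Permutation test for an area effect on one kinematic feature.

    Observed statistic: mean over dogs of (dog-mean feature in the target
    area − dog-mean in the comparison area).  Null: area labels permuted
    within dog × session strata.  p = (1 + #{|stat*| >= |stat|})/(n_perm+1),
    valid (conservative-uniform under the null) by the +1 correction.
    Strata holding a single segment cannot contribute and are logged.
    """
    need = {feature, "dog_id", "session", "sub_label"}
    if not need <= set(feature_df.columns):
        raise ValueError(f"feature table lacks columns {sorted(need - set(feature_df.columns))}")
    df = feature_df[feature_df["sub_label"].isin([target, comparison])]
    if df["dog_id"].nunique() < 2 or df["sub_label"].nunique() < 2:
        raise ValueError("need >= 2 dogs and both areas present")
    vals = df[feature].to_numpy(dtype=float)
    is_target = (df["sub_label"] == target).to_numpy()
    dogs = df["dog_id"].to_numpy()
    dog_list = np.unique(dogs)
    rng = np.random.default_rng(seed)

    # permute labels within dog x session strata
    strata = df.groupby(["dog_id", "session"], sort=True).indices
    labels_perm = np.broadcast_to(is_target, (n_perm, vals.size)).copy()
    singletons = 0
    for idx in strata.values():
        idx = np.asarray(idx)
        if idx.size < 2:
            singletons += 1
            continue
        keys = rng.random((n_perm, idx.size))
        order = np.argsort(keys, axis=1)
        labels_perm[:, idx] = is_target[idx][order]
    if singletons:
        log.info("%d single-segment strata contribute nothing to the null", singletons)

    def dog_mean_diff(lab_matrix):
        # lab_matrix: (R, n) boolean; returns (R,) mean-over-dogs difference
        R = lab_matrix.shape[0]
        diffs = np.zeros(R)
        n_dogs_eff = np.zeros(R)
        for d in dog_list:
            cols = np.flatnonzero(dogs == d)
            v = vals[cols]
            lab = lab_matrix[:, cols]
            nt = lab.sum(axis=1)
            nc = (~lab).sum(axis=1)
            ok = (nt > 0) & (nc > 0)
            mt = np.where(nt > 0, (v * lab).sum(axis=1) / np.maximum(nt, 1), np.nan)
            mc = np.where(nc > 0, (v * ~lab).sum(axis=1) / np.maximum(nc, 1), np.nan)
            diffs += np.where(ok, mt - mc, 0.0)
            n_dogs_eff += ok
        return diffs / np.maximum(n_dogs_eff, 1)

    observed = float(dog_mean_diff(is_target[None, :])[0])
    null = dog_mean_diff(labels_perm)
    p = float((1 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1))
    return observed, p
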