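"""Behavioral creativity scoring and stimulation-effect inference.

Three scores per free-response corpus:

* **originality** — semantic distance between cue and response: phrase
  vectors are composed as the elementwise product of token vectors
  (multiplicative composition), scored as 1 - cosine similarity, bounded in
  [0, 2], and averaged across embedding backends;
* **variability** — total cosine distance: the sum of pairwise distances
  among one subject's response vectors for one item (sentence vectors, i.e.
  token means — cue identity plays no role here);
* **flexibility** — the number of semantic categories a subject's responses
  span, from a 2-D t-SNE embedding of all subjects' responses to the item
  followed by affinity-propagation clustering.

Stimulation effects are tested with paired Wilcoxon signed-rank tests on
subject-level means (stim vs no-stim, plus pairwise block contrasts and a
leave-one-subject-out sensitivity rerun).
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import AffinityPropagation
from sklearn.manifold import TSNE

from .embeddings import EmbeddingProvider, sentence_vector
from .errors import ResponseExcluded, ValidationError

logger = logging.getLogger(__name__)

#: basic English function-word list plus the task-specific additions
#: ("use", "things", "stuff"); stands in for a full NLP stop list.
STOP_WORDS = frozenset("""
a an the and or but if then else of for to in on at by with from as is are was
were be been being am do does did have has had it its this that these those i
you he she we they me him her us them my your his our their what which who
whom not no nor so too very can could would should will shall may might must
use things stuff
""".split())

DEFAULT_ABSENCE_PHRASES = (
    "nothing comes to mind",
    "could not think of anything",
    "can't think of anything",
    "no thoughts",
)

_TOKEN_RE = re.compile(r"[a-z][a-z0-9_]*")


def clean_text(text: str, stop_list: frozenset[str] = STOP_WORDS,
               absence_phrases: tuple[str, ...] = DEFAULT_ABSENCE_PHRASES) -> list[str]:
    """Lowercase, strip punctuation/numbers, drop stop words.

    Raises :class:`ResponseExcluded` for absence-of-thought phrases and for
    responses that are empty after cleaning.
    """
    if not isinstance(text, str):
        raise ResponseExcluded("empty")
    normalized = re.sub(r"[^a-z' ]+", " ", text.lower())
    normalized = re.sub(r"\s+", " ", normalized).strip()
    for phrase in absence_phrases:
        if phrase in normalized or normalized in ("nothing", "i don t know"):
            raise ResponseExcluded("absence-of-thought")
    tokens = [t for t in _TOKEN_RE.findall(text.lower().replace("-", "_"))
              if t not in stop_list]
    if not tokens:
        raise ResponseExcluded("empty")
    return tokens


def _compose_multiplicative(tokens: list[str], provider: EmbeddingProvider
                            ) -> np.ndarray | None:
    vecs = [v for v in (provider.vector(t) for t in tokens) if v is not None]
    if not vecs:
        return None
    out = vecs[0].copy()
    for v in vecs[1:]:
        out *= v
    return out


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("zero-norm vector in cosine distance")
    return float(1.0 - (u @ v) / (nu * nv))


def originality(cue_tokens: list[str], response_tokens: list[str],
                providers: list[EmbeddingProvider]) -> float:
    """Mean across backends of 1 - cosine(cue composition, response
    composition); multiplicative composition, range [0, 2]."""
    scores = []
    for provider in providers:
        cu = _compose_multiplicative(cue_tokens, provider)
        rv = _compose_multiplicative(response_tokens, provider)
        if cu is None or rv is None:
            continue
        scores.append(cosine_distance(cu, rv))
    if not scores:
        raise ResponseExcluded("oov")
    return float(np.mean(scores))


def variability(vectors: list[np.ndarray]) -> float:
    """Total cosine distance over all unordered response pairs.

    A single response yields 0 by convention; zero-norm vectors skip their
    pairs with a warning.
    """
    if len(vectors) < 2:
        logger.info("fewer than 2 responses; variability set to 0")
        return 0.0
    total = 0.0
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            try:
                total += cosine_distance(vectors[i], vectors[j])
            except ValidationError:
                warnings.warn("zero-norm response vector; pair skipped", stacklevel=2)
    return total


def flexibility(vectors: np.ndarray, subjects: list[str], perplexity: float = 5.0,
                learning_rate: float = 1.0, seed: int = 0,
                max_iter: int = 500) -> dict[str, int]:
    """Per-subject count of semantic categories for one item.

    All subjects' response vectors for the item are embedded to 2-D with
    t-SNE and clustered with affinity propagation; each subject's flexibility
    is the number of distinct clusters their responses occupy.  If affinity
    propagation fails to converge, all responses fall into a single cluster
    (with a warning).
    """
    X = np.asarray(vectors, dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("flexibility needs >= 3 pooled responses per item")
    perp = min(perplexity, X.shape[0] - 1)
    emb = TSNE(n_components=2, perplexity=perp, learning_rate=learning_rate,
               random_state=seed, init="pca", max_iter=max_iter).fit_transform(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap = AffinityPropagation(random_state=seed).fit(emb)
    labels = ap.labels_
    if len(ap.cluster_centers_indices_) == 0 or (labels < 0).any():
        warnings.warn("affinity propagation did not converge; single cluster assumed",
                      stacklevel=2)
        labels = np.zeros(X.shape[0], dtype=int)
    out: dict[str, int] = {}
    for subj in set(subjects):
        mask = np.array([s == subj for s in subjects])
        out[subj] = int(len(set(labels[mask])))
    return out


@dataclass
class ScoreTables:
    """Per-response originality plus per item x subject variability and
    flexibility, with block/stimulation metadata carried through."""

    originality: pd.DataFrame
    item_scores: pd.DataFrame
    exclusions: pd.DataFrame


def score_responses(responses: pd.DataFrame, providers: list[EmbeddingProvider],
                    sentence_provider: EmbeddingProvider | None = None,
                    tsne_perplexity: float = 5.0, tsne_learning_rate: float = 1.0,
                    seed: int = 0) -> ScoreTables:
    """Score a response corpus (columns: subject, item, task, block, stim,
    response).

    ``providers`` drive originality (scores averaged across them);
    ``sentence_provider`` (default: the first provider) supplies sentence
    vectors for variability and flexibility.
    """
    sentence_provider = sentence_provider or providers[0]
    orig_rows, excl_rows = [], []
    cleaned: dict[int, list[str]] = {}
    for i, row in responses.iterrows():
        try:
            cue_tokens = clean_text(str(row["item"]))
            resp_tokens = clean_text(str(row["response"]))
            score = originality(cue_tokens, resp_tokens, providers)
        except ResponseExcluded as exc:
            excl_rows.append((row["subject"], row["item"], row["task"],
                              row["block"], row["stim"], row["response"], exc.reason))
            continue
        cleaned[i] = resp_tokens
        orig_rows.append((row["subject"], row["item"], row["task"], row["block"],
                          row["stim"], row["response"], score))
    orig = pd.DataFrame(orig_rows, columns=["subject", "item", "task", "block",
                                            "stim", "response", "originality"])
    exclusions = pd.DataFrame(excl_rows, columns=["subject", "item", "task", "block",
                                                  "stim", "response", "reason"])

    kept = responses.loc[list(cleaned)]
    item_rows = []
    for item, grp in kept.groupby("item", observed=True):
        vecs, subjects, metas = [], [], {}
        for i, row in grp.iterrows():
            v = sentence_vector(sentence_provider, cleaned[i])
            if v is None:
                continue
            vecs.append(v)
            subjects.append(row["subject"])
            metas[row["subject"]] = (row["task"], row["block"], row["stim"])
        if len(vecs) >= 3:
            flex = flexibility(np.vstack(vecs), subjects, perplexity=tsne_perplexity,
                               learning_rate=tsne_learning_rate, seed=seed)
        else:
            flex = {s: 1 for s in set(subjects)}
        for subj in sorted(set(subjects)):
            sv = [v for v, s in zip(vecs, subjects) if s == subj]
            task, block, stim = metas[subj]
            item_rows.append((subj, item, task, block, stim,
                              variability(sv), flex[subj], len(sv)))
    item_scores = pd.DataFrame(item_rows, columns=["subject", "item", "task", "block",
                                                   "stim", "variability",
                                                   "flexibility", "n_responses"])
    return ScoreTables(originality=orig, item_scores=item_scores, exclusions=exclusions)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Paired Wilcoxon signed-rank test; returns (W, p, n_used).

    Zero differences are dropped (Wilcoxon's original convention); W is the
    smaller of the two signed-rank sums; p is exact for n <= 25 and a
    tie-corrected normal approximation otherwise.  If every difference is
    zero, W is NaN and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need >= 2 pairs of equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return float("nan"), 1.0, 0
    method = "exact" if (d.size <= 25 and not _has_rank_ties(d)) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue), int(d.size)


def _has_rank_ties(d: np.ndarray) -> bool:
    a = np.abs(d)
    return len(np.unique(a)) < len(a)


def attention_rates(att: pd.DataFrame) -> pd.DataFrame:
    """Hit/false-alarm rates per ATT condition (reports on mask-only trials
    are false alarms); conditions with zero trials are flagged undefined."""
    rows = []
    for cond, grp in att.groupby("condition", observed=True):
        n = len(grp)
        rate = float(grp["reported"].mean()) if n else float("nan")
        rows.append((cond, n, rate))
    return pd.DataFrame(rows, columns=["condition", "n_trials", "rate"])


_METRICS = (
    ("originality_MW", "originality", "originality", "MW"),
    ("originality_AUT", "originality", "originality", "AUT"),
    ("variability", "item_scores", "variability", "AUT"),
    ("flexibility", "item_scores", "flexibility", "AUT"),
)


def _paired_by(df: pd.DataFrame, value: str, split: str, a, b,
               subject: str = "subject"):
    """Subject-level means for split==a vs split==b, subjects present in both."""
    means = df.groupby([subject, split], observed=True)[value].mean().unstack(split)
    if a not in means.columns or b not in means.columns:
        return None
    means = means[[a, b]].dropna()
    return means if len(means) >= 2 else None


def stimulation_effect_report(scores: ScoreTables, alpha: float = 0.05) -> dict:
    """Paired Wilcoxon tests of the stimulation effect per behavioral metric.

    For each metric: subject-level means by stimulation status, pairwise
    block contrasts (1 vs 2, 2 vs 3, 1 vs 3), and a leave-one-subject-out
    sensitivity rerun of the stim contrast.  Subjects lacking a cell are
    dropped from that contrast (logged).
    """
    report: dict = {"alpha": alpha, "metrics": {}}
    for name, table_name, value, task in _METRICS:
        df = getattr(scores, table_name)
        df = df[df["task"] == task]
        entry: dict = {}
        pairs = _paired_by(df, value, "stim", 0, 1)
        if pairs is None:
            logger.info("metric %s: too few subjects with both stim cells", name)
            entry["stim_vs_nostim"] = None
        else:
            w, p, n = wilcoxon_signed_rank(pairs[0].to_numpy(), pairs[1].to_numpy())
            entry["stim_vs_nostim"] = {
                "W": w, "p": p, "n": n,
                "median_nostim": float(pairs[0].median()),
                "median_stim": float(pairs[1].median()),
            }
            loso = {}
            for subj in pairs.index:
                sub = pairs.drop(index=subj)
                if len(sub) >= 2:
                    w2, p2, n2 = wilcoxon_signed_rank(sub[0].to_numpy(), sub[1].to_numpy())
                    loso[str(subj)] = {"W": w2, "p": p2, "n": n2}
            entry["leave_one_out"] = loso
        blocks = {}
        for a, b in ((1, 2), (2, 3), (1, 3)):
            pb = _paired_by(df, value, "block", a, b)
            if pb is None:
                blocks[f"{a}_vs_{b}"] = None
                continue
            w, p, n = wilcoxon_signed_rank(pb[a].to_numpy(), pb[b].to_numpy())
            blocks[f"{a}_vs_{b}"] = {"W": w, "p": p, "n": n}
        entry["blocks"] = blocks
        report["metrics"][name] = entry
    return report
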