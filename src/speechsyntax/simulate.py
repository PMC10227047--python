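"""Seeded synthetic cohorts: annotated transcripts plus clinical covariates.

No speech corpus is distributed with this package, so analyses are exercised
on synthetic cohorts whose group-level statistics emulate the published
descriptive tables for three groups — schizophrenia spectrum disorder (SSD,
n=34), major depressive disorder (MDD, n=38) and healthy controls (HC, n=40).

Generative model (per participant)
----------------------------------
A latent *syntax severity* ``z ~ N(0, 1)`` (higher = more complex speech)
drives everything that should co-vary:

* sentence category mixture — each sentence is simple, coordinated-only,
  complex-only, or coordinated-and-complex.  The total complex probability is
  tilted on the logit scale by ``severity_complexity_scale * z``; the
  remaining categories are rescaled proportionally.
* subordination depth — a complex sentence embeds ``1 + Poisson(lam)``
  subordinate clauses with ``lam = extra_subordinates_mean *
  exp(c*z - c^2/2)`` (a mean-preserving log-normal tilt,
  ``c = severity_subordination_scale``).
* clause types — each participant gets type propensities drawn from a
  Dirichlet centred on the group type distribution
  (``concentration = type_concentration``).  The Dirichlet heterogeneity is
  what keeps transcript-level syntactic diversity at realistic levels:
  with i.i.d. type draws every speaker would eventually use every frequent
  type, which real speakers do not.
* covariates — six clinical covariates (three verbal-fluency scores, verbal
  episodic memory, negative FTD = SANS alogia, positive FTD = SAPS formal
  thought disorder) are Gaussian with within-domain correlation, coupled to
  ``z`` through ``cross_domain_coupling`` (cognition loads positively,
  FTD negatively).  Bounded instruments (the two FTD scales, >= 0) use a
  zero-censored normal whose latent parameters are moment-matched so the
  censored mean/SD hit the published values.  Education is coupled to ``z``
  separately; age and sex are independent.

Group-level correlation among the five syntax measures is *not* imposed; it
emerges mechanically from the shared latent severity and the sentence-level
sampling process.

Cluster mode replaces the three diagnostic groups by four latent complexity
profiles (extremely / very / moderately / slightly complex) realised as
severity offsets on a pooled parameter set, recording ``cluster_truth``.

Default parameters were calibrated once by simulation so cohort means of the
five headline measures and the six covariates sit within half a printed SD
of the published group values at the published sample sizes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .metrics import SyntaxProfile, compute_syntax_profile
from .types import CLAUSE_TYPES, ClauseType, SentenceAnnotation, Transcript

GROUPS = ("SSD", "MDD", "HC")

COVARIATE_NAMES = (
    "semantic_vf",
    "phonemic_vf",
    "alternating_vf",
    "verbal_episodic_memory",
    "neg_ftd",
    "pos_ftd",
)
NEUROPSYCH_NAMES = COVARIATE_NAMES[:4]
PSYCHOPATH_NAMES = COVARIATE_NAMES[4:]
DEMOGRAPHIC_NAMES = ("age", "sex", "education")

#: Direction in which latent syntax severity loads on each covariate
#: (+1: more complex speech, better score; -1: more complex speech, less FTD).
COVARIATE_DIRECTIONS = {
    "semantic_vf": 1.0,
    "phonemic_vf": 1.0,
    "alternating_vf": 1.0,
    "verbal_episodic_memory": 1.0,
    "neg_ftd": -1.0,
    "pos_ftd": -1.0,
}

# ---------------------------------------------------------------------------
# Published group statistics used as calibration targets (mean, SD).
# ---------------------------------------------------------------------------

#: (measure, group) -> (mean, sd) for the linguistic measures.
SYNTAX_TARGETS: Dict[Tuple[str, str], Tuple[float, float]] = {}


def _fill_targets(measure: str, triple: Sequence[Tuple[float, float]]) -> None:
    for group, (m, s) in zip(GROUPS, triple):
        SYNTAX_TARGETS[(measure, group)] = (m, s)


_fill_targets("total_words", [(1023.47, 428.4), (1157.76, 333.6), (1148.25, 306.82)])
_fill_targets("total_sentences", [(77.0, 35.34), (63.58, 19.83), (65.35, 16.68)])
_fill_targets("mlu", [(13.8, 3.74), (18.76, 4.74), (17.91, 4.18)])
_fill_targets("total_different_words", [(320.79, 108.61), (372.42, 80.77), (370.95, 90.55)])
_fill_targets("ttr", [(0.33, 0.05), (0.33, 0.05), (0.33, 0.04)])
_fill_targets("rate_simple", [(0.35, 0.09), (0.22, 0.08), (0.23, 0.08)])
_fill_targets("rate_coordinated", [(0.48, 0.13), (0.63, 0.12), (0.63, 0.10)])
_fill_targets("relative_sum_sub", [(0.33, 0.11), (0.43, 0.13), (0.41, 0.12)])
_fill_targets("extended_relative_sum_sub", [(0.48, 0.23), (0.71, 0.33), (0.68, 0.28)])
_fill_targets("pure_syntactic_complexity", [(1.43, 0.26), (1.62, 0.37), (1.64, 0.28)])
_fill_targets("weighted_sum_sub", [(0.74, 0.45), (1.26, 0.91), (1.21, 0.65)])
_fill_targets("syntactic_diversity", [(0.52, 0.13), (0.62, 0.13), (0.63, 0.14)])

#: (covariate, group) -> (mean, sd) for the clinical covariates.
COVARIATE_TARGETS: Dict[Tuple[str, str], Tuple[float, float]] = {}
for _name, _triple in {
    "semantic_vf": [(18.94, 5.45), (23.47, 5.43), (22.51, 4.39)],
    "phonemic_vf": [(10.00, 4.46), (11.18, 4.24), (10.66, 3.93)],
    "alternating_vf": [(11.63, 3.75), (14.74, 3.10), (15.63, 2.41)],
    "verbal_episodic_memory": [(46.16, 8.23), (59.58, 8.20), (58.94, 9.72)],
    "neg_ftd": [(2.55, 2.65), (0.66, 1.07), (0.16, 0.53)],
    "pos_ftd": [(7.09, 8.19), (1.08, 1.96), (0.28, 0.96)],
    "age": [(42.47, 13.11), (40.82, 13.03), (40.83, 13.35)],
    "education": [(12.00, 2.32), (13.11, 2.56), (14.79, 2.65)],
}.items():
    for _group, (_m, _s) in zip(GROUPS, _triple):
        COVARIATE_TARGETS[(_name, _group)] = (_m, _s)

#: Published group sizes.
GROUP_SIZES = {"SSD": 34, "MDD": 38, "HC": 40}

_P_FEMALE = {"SSD": 10 / 34, "MDD": 26 / 38, "HC": 25 / 40}


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one group's transcripts."""

    group_label: str
    n_participants: int
    sentence_count_mean: float
    sentence_count_sd: float
    tokens_per_sentence_mean: float
    tokens_per_sentence_sd: float
    tokens_between_sd: float
    p_simple: float
    p_coordinated_only: float
    p_complex_only: float
    p_coordinated_and_complex: float
    extra_subordinates_mean: float
    type_distribution: Tuple[float, ...]
    type_concentration: float
    vocabulary_size: int
    zipf_exponent: float
    severity_complexity_scale: float = 0.45
    severity_subordination_scale: float = 0.5
    severity_subordination_corr: float = 0.4
    type_repeat_prob: float = 0.15

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in ("sentence_count_mean", "sentence_count_sd", "tokens_per_sentence_mean",
                     "tokens_per_sentence_sd", "vocabulary_size", "zipf_exponent",
                     "type_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.extra_subordinates_mean < 0:
            raise ValueError("extra_subordinates_mean must be non-negative")
        mix = (self.p_simple, self.p_coordinated_only, self.p_complex_only,
               self.p_coordinated_and_complex)
        if any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("sentence-category probabilities must be non-negative and sum to 1")
        td = tuple(float(x) for x in self.type_distribution)
        if len(td) != len(CLAUSE_TYPES):
            raise ValueError(f"type_distribution needs {len(CLAUSE_TYPES)} entries")
        if any(p < 0 for p in td) or abs(sum(td) - 1.0) > 1e-9:
            raise ValueError("type_distribution must be non-negative and sum to 1")
        object.__setattr__(self, "type_distribution", td)

    @property
    def p_complex(self) -> float:
        return self.p_complex_only + self.p_coordinated_and_complex


def _censored_normal_params(mean: float, sd: float) -> Tuple[float, float]:
    """Latent (mu, sigma) so that max(0, N(mu, sigma)) has the given mean/SD."""

    def moments(mu: float, sigma: float) -> Tuple[float, float]:
        a = mu / sigma
        phi, Phi = stats.norm.pdf(a), stats.norm.cdf(a)
        m1 = mu * Phi + sigma * phi
        m2 = (mu * mu + sigma * sigma) * Phi + mu * sigma * phi
        return m1, math.sqrt(max(m2 - m1 * m1, 1e-12))

    def resid(x):
        m1, s1 = moments(x[0], math.exp(x[1]))
        return [m1 - mean, s1 - sd]

    x0 = [mean, math.log(sd)]
    sol, info, ier, _ = optimize.fsolve(resid, x0, full_output=True)
    if ier != 1 or max(abs(v) for v in info["fvec"]) > 1e-6:
        return mean, sd  # fall back to plain clipping
    return float(sol[0]), float(math.exp(sol[1]))


@dataclass(frozen=True)
class CovariateParams:
    """Clinical covariate and demographic generator for one group."""

    group_label: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    within_domain_correlation: float = 0.4
    cross_domain_coupling: float = 0.3
    education_severity_coupling: float = 0.75
    age_mean: float = 41.0
    age_sd: float = 13.0
    education_mean: float = 13.5
    education_sd: float = 2.5
    p_female: float = 0.5
    censored: Tuple[str, ...] = ("neg_ftd", "pos_ftd")

    def __post_init__(self) -> None:
        missing = [n for n in COVARIATE_NAMES if n not in self.means or n not in self.sds]
        if missing:
            raise ValueError(f"missing covariate parameters for {missing}")
        if not 0 <= self.within_domain_correlation < 1:
            raise ValueError("within_domain_correlation must be in [0, 1)")
        if not -1 <= self.cross_domain_coupling <= 1:
            raise ValueError("cross_domain_coupling must be in [-1, 1]")
        corr = self.residual_correlation()
        eigmin = float(np.linalg.eigvalsh(corr).min())
        if eigmin <= 0:
            raise ValueError(f"implied covariance is not positive definite (min eig {eigmin:g})")
        latent = {}
        for name in self.censored:
            latent[name] = _censored_normal_params(self.means[name], self.sds[name])
        object.__setattr__(self, "_latent", latent)
        object.__setattr__(self, "_chol", np.linalg.cholesky(corr))

    def residual_correlation(self) -> np.ndarray:
        """Correlation of the non-severity residuals (block within-domain)."""
        k = len(COVARIATE_NAMES)
        corr = np.eye(k)
        rho = self.within_domain_correlation
        for block in (NEUROPSYCH_NAMES, PSYCHOPATH_NAMES):
            idx = [COVARIATE_NAMES.index(n) for n in block]
            for i in idx:
                for j in idx:
                    if i != j:
                        corr[i, j] = rho
        return corr


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group_label: str
    transcript: Transcript
    profile: SyntaxProfile
    covariates: Dict[str, float]
    demographics: Dict[str, float]
    severity: float
    cluster_truth: Optional[int] = None


# ---------------------------------------------------------------------------
# Default (calibrated) parameters
# ---------------------------------------------------------------------------

# Sentence-category mixtures solve:  simple + coordinated + complex - overlap = 1
# with the published simple/coordinated/complex rates, giving the overlap
# (coordinated-and-complex) probability directly.
_TYPE_WEIGHTS = {
    # order: temporal, local, modal, causal, conditional, adversative, final,
    #        consecutive, concessive, comparative, relative, complement, indirect_question
    # Types printed as 0.00 in the group table keep a small positive floor.
    "SSD": (0.006, 0.010, 0.006, 0.050, 0.020, 0.006, 0.010, 0.010, 0.006, 0.050,
            0.090, 0.110, 0.060),
    "MDD": (0.013, 0.013, 0.013, 0.070, 0.030, 0.006, 0.020, 0.020, 0.013, 0.070,
            0.130, 0.150, 0.070),
    "HC": (0.010, 0.014, 0.014, 0.070, 0.030, 0.007, 0.020, 0.013, 0.014, 0.070,
           0.140, 0.150, 0.060),
}


def _normalised(weights: Sequence[float]) -> Tuple[float, ...]:
    total = float(sum(weights))
    return tuple(float(w) / total for w in weights)


# Calibrated once by simulation (scratch tuning at n=4000); see docs/methods.md.
_GROUP_DEFAULTS: Dict[str, Dict[str, object]] = {
    "SSD": dict(
        n_participants=34,
        sentence_count_mean=77.0, sentence_count_sd=35.34,
        tokens_per_sentence_mean=13.8, tokens_per_sentence_sd=6.5, tokens_between_sd=3.5,
        p_complex=0.3205, p_overlap=0.155, rate_coordinated=0.48,
        extra_subordinates_mean=0.421,
        type_weights=_TYPE_WEIGHTS["SSD"], type_concentration=15.0,
        type_repeat_prob=0.10,
        vocabulary_size=5000, zipf_exponent=1.15,
    ),
    "MDD": dict(
        n_participants=38,
        sentence_count_mean=63.58, sentence_count_sd=19.83,
        tokens_per_sentence_mean=18.76, tokens_per_sentence_sd=7.5, tokens_between_sd=4.4,
        p_complex=0.4246, p_overlap=0.275, rate_coordinated=0.63,
        extra_subordinates_mean=0.616,
        type_weights=_TYPE_WEIGHTS["MDD"], type_concentration=22.0,
        type_repeat_prob=0.12,
        vocabulary_size=5000, zipf_exponent=1.15,
    ),
    "HC": dict(
        n_participants=40,
        sentence_count_mean=65.35, sentence_count_sd=16.68,
        tokens_per_sentence_mean=17.91, tokens_per_sentence_sd=7.0, tokens_between_sd=3.9,
        p_complex=0.4062, p_overlap=0.265, rate_coordinated=0.63,
        extra_subordinates_mean=0.642,
        type_weights=_TYPE_WEIGHTS["HC"], type_concentration=26.0,
        type_repeat_prob=0.12,
        vocabulary_size=5000, zipf_exponent=1.15,
    ),
}


def default_group_params(group_label: str) -> Tuple[GroupParams, CovariateParams]:
    """Calibrated default parameters for one of SSD, MDD, HC."""
    if group_label not in _GROUP_DEFAULTS:
        raise ValueError(f"unknown group label {group_label!r}; expected one of {GROUPS}")
    d = _GROUP_DEFAULTS[group_label]
    pc = float(d["p_complex"])
    overlap = float(d["p_overlap"])
    coord = float(d["rate_coordinated"])
    p_coordinated_only = coord - overlap
    p_complex_only = pc - overlap
    p_simple = 1.0 - p_coordinated_only - p_complex_only - overlap
    gp = GroupParams(
        group_label=group_label,
        n_participants=int(d["n_participants"]),
        sentence_count_mean=float(d["sentence_count_mean"]),
        sentence_count_sd=float(d["sentence_count_sd"]),
        tokens_per_sentence_mean=float(d["tokens_per_sentence_mean"]),
        tokens_per_sentence_sd=float(d["tokens_per_sentence_sd"]),
        tokens_between_sd=float(d["tokens_between_sd"]),
        p_simple=p_simple,
        p_coordinated_only=p_coordinated_only,
        p_complex_only=p_complex_only,
        p_coordinated_and_complex=overlap,
        extra_subordinates_mean=float(d["extra_subordinates_mean"]),
        type_distribution=_normalised(d["type_weights"]),  # type: ignore[arg-type]
        type_concentration=float(d["type_concentration"]),
        type_repeat_prob=float(d["type_repeat_prob"]),
        vocabulary_size=int(d["vocabulary_size"]),
        zipf_exponent=float(d["zipf_exponent"]),
    )
    cp = CovariateParams(
        group_label=group_label,
        means={n: COVARIATE_TARGETS[(n, group_label)][0] for n in COVARIATE_NAMES},
        sds={n: COVARIATE_TARGETS[(n, group_label)][1] for n in COVARIATE_NAMES},
        age_mean=COVARIATE_TARGETS[("age", group_label)][0],
        age_sd=COVARIATE_TARGETS[("age", group_label)][1],
        education_mean=COVARIATE_TARGETS[("education", group_label)][0],
        education_sd=COVARIATE_TARGETS[("education", group_label)][1],
        p_female=_P_FEMALE[group_label],
    )
    return gp, cp


def pooled_group_params() -> Tuple[GroupParams, CovariateParams]:
    """Size-weighted pooling of the three group defaults (cluster-mode base)."""
    parts = [default_group_params(g) for g in GROUPS]
    weights = np.array([GROUP_SIZES[g] for g in GROUPS], dtype=float)
    weights /= weights.sum()

    def avg(get) -> float:
        return float(sum(w * get(gp) for w, (gp, _) in zip(weights, parts)))

    type_dist = _normalised(
        np.sum([w * np.array(gp.type_distribution) for w, (gp, _) in zip(weights, parts)], axis=0)
    )
    gp0 = parts[0][0]
    gp = GroupParams(
        group_label="POOLED",
        n_participants=sum(GROUP_SIZES.values()),
        sentence_count_mean=avg(lambda g: g.sentence_count_mean),
        sentence_count_sd=avg(lambda g: g.sentence_count_sd),
        tokens_per_sentence_mean=avg(lambda g: g.tokens_per_sentence_mean),
        tokens_per_sentence_sd=avg(lambda g: g.tokens_per_sentence_sd),
        tokens_between_sd=avg(lambda g: g.tokens_between_sd),
        p_simple=avg(lambda g: g.p_simple),
        p_coordinated_only=avg(lambda g: g.p_coordinated_only),
        p_complex_only=avg(lambda g: g.p_complex_only),
        p_coordinated_and_complex=1.0
        - avg(lambda g: g.p_simple)
        - avg(lambda g: g.p_coordinated_only)
        - avg(lambda g: g.p_complex_only),
        extra_subordinates_mean=avg(lambda g: g.extra_subordinates_mean),
        type_distribution=type_dist,
        type_concentration=gp0.type_concentration,
        vocabulary_size=gp0.vocabulary_size,
        zipf_exponent=gp0.zipf_exponent,
    )
    cp = CovariateParams(
        group_label="POOLED",
        means={n: float(np.dot(weights, [p[1].means[n] for p in parts])) for n in COVARIATE_NAMES},
        sds={n: float(np.dot(weights, [p[1].sds[n] for p in parts])) for n in COVARIATE_NAMES},
        age_mean=avg(lambda g: 0) + float(np.dot(weights, [p[1].age_mean for p in parts])),
        age_sd=float(np.dot(weights, [p[1].age_sd for p in parts])),
        education_mean=float(np.dot(weights, [p[1].education_mean for p in parts])),
        education_sd=float(np.dot(weights, [p[1].education_sd for p in parts])),
        p_female=float(np.dot(weights, [p[1].p_female for p in parts])),
    )
    return gp, cp


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

_zipf_cache: Dict[Tuple[int, float], np.ndarray] = {}
_vocab_cache: Dict[int, np.ndarray] = {}


def _zipf_cumprobs(size: int, exponent: float) -> np.ndarray:
    key = (size, round(exponent, 10))
    if key not in _zipf_cache:
        ranks = np.arange(1, size + 1, dtype=float)
        p = ranks ** -exponent
        _zipf_cache[key] = np.cumsum(p / p.sum())
    return _zipf_cache[key]


def _vocab(size: int) -> np.ndarray:
    if size not in _vocab_cache:
        _vocab_cache[size] = np.array([f"w{i:05d}" for i in range(size)])
    return _vocab_cache[size]


def _tilted_category_probs(params: GroupParams, severity: float) -> np.ndarray:
    """Shift total complex probability on the logit scale; rescale the rest."""
    pc = params.p_complex
    if pc <= 0.0 or pc >= 1.0:  # degenerate mixtures cannot be tilted
        return np.array([params.p_simple, params.p_coordinated_only,
                         params.p_complex_only, params.p_coordinated_and_complex])
    logit = math.log(pc / (1.0 - pc)) + params.severity_complexity_scale * severity
    pc_z = 1.0 / (1.0 + math.exp(-logit))
    f_complex = pc_z / pc
    f_other = (1.0 - pc_z) / (1.0 - pc)
    probs = np.array(
        [
            params.p_simple * f_other,
            params.p_coordinated_only * f_other,
            params.p_complex_only * f_complex,
            params.p_coordinated_and_complex * f_complex,
        ]
    )
    return probs / probs.sum()


def sample_transcript(
    params: GroupParams,
    rng: np.random.Generator,
    participant_id: str = "p000",
    severity: float = 0.0,
    type_probs: Optional[np.ndarray] = None,
    with_tokens: bool = True,
) -> Transcript:
    """Draw one annotated transcript.

    ``severity`` is the participant's latent syntax-severity value;
    ``type_probs`` are participant-specific clause-type propensities (drawn
    from the group Dirichlet when omitted).  ``with_tokens=False`` skips word
    sampling (token counts only), for large simulations where lexical
    descriptives are not needed.
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("rng must be a numpy Generator (seeded)")
    n_sentences = max(5, int(round(rng.normal(params.sentence_count_mean,
                                              params.sentence_count_sd))))
    if type_probs is None:
        alpha = params.type_concentration * np.asarray(params.type_distribution)
        type_probs = rng.dirichlet(np.maximum(alpha, 1e-6))
    cat_probs = _tilted_category_probs(params, severity)
    categories = rng.choice(4, size=n_sentences, p=cat_probs)

    mlu_i = max(2.0, rng.normal(params.tokens_per_sentence_mean, params.tokens_between_sd))
    token_counts = np.maximum(
        1, np.round(rng.normal(mlu_i, params.tokens_per_sentence_sd, size=n_sentences))
    ).astype(int)

    # Subordination depth has its own participant-level heterogeneity, only
    # partially aligned with severity (a fully shared driver would inflate the
    # covariance between complex-sentence rate and clauses-per-complex-sentence
    # beyond what the published extended relative sum implies).
    rho = params.severity_subordination_corr
    depth_z = rho * severity + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    lam = params.extra_subordinates_mean * math.exp(
        params.severity_subordination_scale * depth_z
        - 0.5 * params.severity_subordination_scale ** 2
    )

    words = None
    if with_tokens:
        cum = _zipf_cumprobs(params.vocabulary_size, params.zipf_exponent)
        vocab = _vocab(params.vocabulary_size)
        total_tokens = int(token_counts.sum())
        word_idx = np.searchsorted(cum, rng.random(total_tokens), side="right")
        words = vocab[word_idx]

    sentences = []
    offset = 0
    for cat, count in zip(categories, token_counts):
        toks = tuple(words[offset:offset + count]) if words is not None else None
        offset += count
        is_complex = cat >= 2
        clauses: Dict[str, int] = {}
        if is_complex:
            n_clauses = 1 + rng.poisson(lam)
            # Speakers reuse a construction within a sentence: each clause after
            # the first repeats an already-used type with type_repeat_prob.
            drawn: List[int] = [int(rng.choice(len(CLAUSE_TYPES), p=type_probs))]
            for _ in range(n_clauses - 1):
                if rng.random() < params.type_repeat_prob:
                    drawn.append(drawn[int(rng.integers(len(drawn)))])
                else:
                    drawn.append(int(rng.choice(len(CLAUSE_TYPES), p=type_probs)))
            for t in drawn:
                label = CLAUSE_TYPES[t].value
                clauses[label] = clauses.get(label, 0) + 1
        sentences.append(
            SentenceAnnotation(
                token_count=int(count),
                is_coordinated=cat in (1, 3),
                subordinate_clauses=clauses,  # type: ignore[arg-type]
                tokens=toks,
            )
        )
    return Transcript(participant_id, tuple(sentences))


def _sample_covariates(
    cp: CovariateParams, severity: float, rng: np.random.Generator
) -> Tuple[Dict[str, float], Dict[str, float]]:
    kappa = cp.cross_domain_coupling
    eps = cp._chol @ rng.standard_normal(len(COVARIATE_NAMES))  # type: ignore[attr-defined]
    resid_scale = math.sqrt(max(0.0, 1.0 - kappa * kappa))
    covariates: Dict[str, float] = {}
    for i, name in enumerate(COVARIATE_NAMES):
        u = kappa * COVARIATE_DIRECTIONS[name] * severity + resid_scale * eps[i]
        if name in cp.censored:
            mu, sig = cp._latent[name]  # type: ignore[attr-defined]
            covariates[name] = max(0.0, mu + sig * u)
        else:
            covariates[name] = cp.means[name] + cp.sds[name] * u
    rho_e = cp.education_severity_coupling
    edu = cp.education_mean + cp.education_sd * (
        rho_e * severity + math.sqrt(1 - rho_e * rho_e) * rng.standard_normal()
    )
    demographics = {
        "age": float(np.clip(rng.normal(cp.age_mean, cp.age_sd), 18.0, 70.0)),
        "sex": float(rng.random() < cp.p_female),
        "education": float(max(8.0, edu)),
    }
    return covariates, demographics


@dataclass(frozen=True)
class ClusterModeConfig:
    """Four latent complexity profiles on a pooled parameter base."""

    n_total: int = 112
    proportions: Tuple[float, ...] = (39 / 112, 19 / 112, 20 / 112, 34 / 112)
    severity_offsets: Tuple[float, ...] = (2.7, 1.3, -0.7, -3.4)
    within_profile_sd: float = 0.1
    cross_domain_coupling: float = 0.6
    #: in cluster mode the latent profile drives subordination depth fully,
    #: so the planted partition is identifiable from the syntax features
    severity_subordination_corr: float = 1.0

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if len(self.proportions) != len(self.severity_offsets):
            raise ValueError("proportions and severity_offsets must have equal length")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or any(p <= 0 for p in self.proportions):
            raise ValueError("proportions must be positive and sum to 1")
        if list(self.severity_offsets) != sorted(self.severity_offsets, reverse=True):
            raise ValueError("severity_offsets must be in descending (most complex first) order")


@dataclass(frozen=True)
class CohortConfig:
    """Either diagnostic-group mode (default 34/38/40) or cluster mode."""

    groups: Tuple[Tuple[str, int], ...] = (("SSD", 34), ("MDD", 38), ("HC", 40))
    cluster_mode: Optional[ClusterModeConfig] = None
    cross_domain_coupling: Optional[float] = None
    with_tokens: bool = True

    @staticmethod
    def from_dict(d: Mapping[str, object]) -> "CohortConfig":
        if "cluster_mode" in d and d["cluster_mode"]:
            cm = d["cluster_mode"]
            if cm is True:
                cm = {}
            return CohortConfig(cluster_mode=ClusterModeConfig(**dict(cm)))  # type: ignore[arg-type]
        groups = d.get("groups")
        if groups is None:
            return CohortConfig()
        pairs = tuple((str(g["label"]), int(g["n"])) if isinstance(g, Mapping) else (str(g[0]), int(g[1]))
                      for g in groups)  # type: ignore[index]
        return CohortConfig(groups=pairs,
                            cross_domain_coupling=d.get("cross_domain_coupling"))  # type: ignore[arg-type]


def sample_cohort(config: CohortConfig | None = None, seed: int = 0) -> List[ParticipantRecord]:
    """Draw a full cohort.  Per-participant streams derive from the master seed,
    so cohorts are reproducible under subsetting."""
    config = config or CohortConfig()
    master = np.random.SeedSequence(seed)

    records: List[ParticipantRecord] = []
    if config.cluster_mode is not None:
        cm = config.cluster_mode
        gp, cp = pooled_group_params()
        gp = replace(gp, severity_subordination_corr=cm.severity_subordination_corr)
        cp = replace(cp, cross_domain_coupling=cm.cross_domain_coupling)
        children = master.spawn(cm.n_total)
        props = np.asarray(cm.proportions)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            profile_idx = int(rng.choice(len(props), p=props))
            z = rng.normal(cm.severity_offsets[profile_idx], cm.within_profile_sd)
            pid = f"P{i:03d}"
            transcript = sample_transcript(gp, rng, pid, severity=z,
                                           with_tokens=config.with_tokens)
            covs, demo = _sample_covariates(cp, z, rng)
            records.append(
                ParticipantRecord(
                    participant_id=pid, group_label="POOLED", transcript=transcript,
                    profile=compute_syntax_profile(transcript), covariates=covs,
                    demographics=demo, severity=z, cluster_truth=profile_idx + 1,
                )
            )
        return records

    for label, n in config.groups:
        if n <= 0:
            raise ValueError(f"group {label!r} has non-positive n")
        gp, cp = default_group_params(label)
        if config.cross_domain_coupling is not None:
            cp = replace(cp, cross_domain_coupling=config.cross_domain_coupling)
        label_key = zlib.crc32(label.encode()) % (2 ** 31)
        children = np.random.SeedSequence((seed, label_key)).spawn(n)
        for i, child in enumerate(children):
            rng = np.random.default_rng(child)
            z = rng.normal()
            pid = f"{label}{i:03d}"
            transcript = sample_transcript(gp, rng, pid, severity=z,
                                           with_tokens=config.with_tokens)
            covs, demo = _sample_covariates(cp, z, rng)
            records.append(
                ParticipantRecord(
                    participant_id=pid, group_label=label, transcript=transcript,
                    profile=compute_syntax_profile(transcript), covariates=covs,
                    demographics=demo, severity=z,
                )
            )
    return records


def cohort_frame(records: Sequence[ParticipantRecord]):
    """Flatten a cohort to a DataFrame (profiles + covariates + demographics)."""
    import pandas as pd

    rows = []
    for r in records:
        row: Dict[str, object] = {"participant_id": r.participant_id, "group": r.group_label}
        if r.cluster_truth is not None:
            row["cluster_truth"] = r.cluster_truth
        row.update(r.profile.as_row())
        row.update(r.covariates)
        row.update(r.demographics)
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_report(
    records: Sequence[ParticipantRecord],
    targets: Optional[Mapping[Tuple[str, str], Tuple[float, float]]] = None,
):
    """Compare cohort means against target (mean, sd) pairs keyed by (measure, group)."""
    import pandas as pd

    if not records:
        raise ValueError("empty cohort")
    if targets is None:
        targets = {k: v for k, v in SYNTAX_TARGETS.items()}
    frame = cohort_frame(records)
    rows = []
    for (measure, group), (t_mean, t_sd) in targets.items():
        if measure not in frame.columns or group not in set(frame["group"]):
            raise KeyError(f"calibration target ({measure!r}, {group!r}) not present in cohort")
        sample_mean = float(frame.loc[frame["group"] == group, measure].mean())
        rows.append(
            {
                "measure": measure,
                "group": group,
                "sample_mean": sample_mean,
                "target_mean": t_mean,
                "target_sd": t_sd,
                "z": (sample_mean - t_mean) / t_sd,
            }
        )
    return pd.DataFrame(rows)
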