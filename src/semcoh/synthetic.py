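"""Synthetic study generator with planted ground truth.

Every input the analysis pipeline consumes can be generated here: a
topic-structured background corpus, annotated speech transcripts with a
tunable off-topic drift rate, a psycholinguistic norms table with a planted
four-factor structure, and Bernoulli accuracy trials from a factorial
logistic model.  Generators are pure functions of their spec and seed, and
ground truth is always returned (and serialized) alongside the data.

Topic geometry
--------------
Topics sit on a ring.  Each topic owns a disjoint core vocabulary but its
word distribution also draws on nearby topics' cores with decaying weight,
so adjacent topics are semantically related while distant topics are
unrelated.  "Smooth" drift
moves to an adjacent topic through a gradual mixture ramp (the hallmark of
connected speech that wanders off-topic without abrupt breaks); "abrupt"
drift jumps instantly to a uniformly random topic.  Impaired speakers are
emulated by raising the drift probability and shortening responses — never
by editing vectors after the fact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .transcripts import Transcript, serialize_transcript

__all__ = [
    "TopicModelSpec",
    "TopicModel",
    "DriftSpec",
    "build_topics",
    "gen_corpus",
    "gen_response",
    "gen_norms",
    "gen_factor_measures",
    "gen_accuracy",
    "gen_lmm_data",
    "StudyData",
    "make_study",
    "write_study",
]

# Small closed-class lexicon used when responses interleave function words;
# all entries are in the packaged English function-word list and absent
# from the topic vocabularies (hence out-of-vocabulary for the space).
FUNCTION_WORDS = (
    "the a an and of to in it is was that he she they we you i on for with "
    "at by from as but or so if then there this those these not are were be"
).split()

_COMMENT_PHRASES = [
    "i do n't know the word",
    "i ca n't think of it",
    "what is it called",
]


@dataclass(frozen=True)
class TopicModelSpec:
    """Parameters of the ring-structured topic model.

    Each topic owns a disjoint core vocabulary of ``vocab_per_topic`` words.
    A topic's word distribution also draws on the first ``shared_vocab``
    words of each neighbouring topic's core, out to ring distance
    ``len(neighbor_weights)``, with the per-side probability masses given by
    ``neighbor_weights``.  This makes ring-adjacent topics semantically
    close (gradual topic drift stays locally coherent) while distant topics
    are unrelated.
    """

    n_topics: int = 20
    vocab_per_topic: int = 200
    shared_vocab: int = 200
    topic_word_concentration: float = 1.0
    neighbor_weights: tuple[float, ...] = (0.26, 0.11, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if 2.0 * sum(self.neighbor_weights) >= 1.0:
            raise ValueError("neighbour masses must leave mass for the core")


@dataclass
class TopicModel:
    """Realized topic-word distributions over a finite vocabulary."""

    spec: TopicModelSpec
    vocabulary: list[str]
    topic_dists: np.ndarray           # n_topics x |V|, rows sum to 1

    @property
    def n_topics(self) -> int:
        return self.spec.n_topics

    def sample_tokens(self, topic: int, n: int, rng: np.random.Generator) -> list[str]:
        idx = rng.choice(len(self.vocabulary), size=n, p=self.topic_dists[topic])
        return [self.vocabulary[i] for i in idx]


def build_topics(spec: TopicModelSpec) -> TopicModel:
    """Construct topic-word distributions from a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    K, C = spec.n_topics, spec.vocab_per_topic
    S = min(spec.shared_vocab, C)
    vocabulary = [f"t{k:02d}w{i:03d}" for k in range(K) for i in range(C)]
    # each core block has a fixed within-block weight profile, seen
    # identically by every topic that draws on it
    block_weights = [
        rng.dirichlet(np.full(C, spec.topic_word_concentration))
        for _ in range(K)
    ]
    span = len(spec.neighbor_weights) if (K > 1 and S > 0) else 0
    span = min(span, (K - 1) // 2)
    core_mass = 1.0 - 2.0 * sum(spec.neighbor_weights[:span])

    dists = np.zeros((K, len(vocabulary)))
    for k in range(K):
        contributions = [(k, core_mass, C)]
        for d in range(1, span + 1):
            mass = spec.neighbor_weights[d - 1]
            contributions.append(((k + d) % K, mass, S))
            contributions.append(((k - d) % K, mass, S))
        for kk, mass, width in contributions:
            w = block_weights[kk][:width]
            dists[k, kk * C : kk * C + width] += mass * w / w.sum()
        dists[k] /= dists[k].sum()
    return TopicModel(spec=spec, vocabulary=vocabulary, topic_dists=dists)


def gen_corpus(
    topics: TopicModel,
    n_docs: int = 400,
    doc_length: int = 150,
    seed: int = 0,
) -> tuple[list[list[str]], list[int]]:
    """Topic-homogeneous documents for training the semantic space.

    Each document draws a single topic (cycling through all topics so every
    topic is represented, with the remainder uniform) and samples its tokens
    from that topic's word distribution.
    """
    rng = np.random.default_rng(seed)
    K = topics.n_topics
    doc_topics = [i % K for i in range(n_docs)]
    rng.shuffle(doc_topics)
    docs = [topics.sample_tokens(t, doc_length, rng) for t in doc_topics]
    return docs, doc_topics


# ---------------------------------------------------------------------------
# Drifting responses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DriftSpec:
    """How a single simulated response wanders off-topic.

    ``drift_prob`` is evaluated at every ``window``-token boundary; when a
    drift fires, a smooth speaker starts a gradual mixture ramp (length
    ``transition_len`` tokens) toward a ring-adjacent topic, while an abrupt
    speaker jumps instantly to a uniformly random topic.
    ``function_word_rate`` interleaves closed-class words, which are absent
    from the space vocabulary but still occupy window positions.
    """

    prompt_topic: int = 0
    drift_prob: float = 0.0
    switch_style: str = "smooth"      # or "abrupt"
    target_length: int = 120
    window: int = 20
    transition_len: int = 200
    function_word_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drift_prob <= 1.0:
            raise ValueError("drift_prob must lie in [0, 1]")
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")
        if self.switch_style not in ("smooth", "abrupt"):
            raise ValueError(f"unknown switch_style: {self.switch_style!r}")


def gen_response(
    spec: DriftSpec, topics: TopicModel
) -> tuple[list[str], list[int]]:
    """Simulate one response; returns (tokens, per-token topic trajectory).

    The trajectory records the dominant topic at each token (ground truth
    for validating the coherence measures).
    """
    if not 0 <= spec.prompt_topic < topics.n_topics:
        raise ValueError("prompt_topic must be one of the model's topics")
    rng = np.random.default_rng(spec.seed)
    K = topics.n_topics
    from_topic = to_topic = spec.prompt_topic
    ramp = 0.0                         # mixture weight on to_topic
    ramp_step = 1.0 / max(spec.transition_len, 1)

    tokens: list[str] = []
    trajectory: list[int] = []
    content_count = 0
    blend_acc = 0.0                    # error-diffusion accumulator
    while len(tokens) < spec.target_length:
        if (
            content_count > 0
            and content_count % spec.window == 0
            and rng.random() < spec.drift_prob
        ):
            if spec.switch_style == "abrupt":
                from_topic = to_topic = int(rng.integers(K))
                ramp = 0.0
            elif from_topic == to_topic:
                # smooth speakers finish a gradual transition before
                # drifting again; a drift event mid-ramp is ignored
                step = 1 if rng.random() < 0.5 else -1
                to_topic = (from_topic + step) % K
                ramp = 0.0
        if spec.function_word_rate > 0 and rng.random() < spec.function_word_rate:
            tokens.append(FUNCTION_WORDS[int(rng.integers(len(FUNCTION_WORDS)))])
            trajectory.append(to_topic if ramp >= 0.5 else from_topic)
            continue
        if from_topic != to_topic:
            ramp = min(1.0, ramp + ramp_step)
            if ramp >= 1.0:
                from_topic, ramp, blend_acc = to_topic, 0.0, 0.0
        if from_topic != to_topic:
            # deterministic error-diffusion blend: the share of new-topic
            # tokens in any span tracks the ramp closely, avoiding the
            # extra window-composition noise a Bernoulli draw would add
            blend_acc += ramp
            if blend_acc >= 1.0:
                blend_acc -= 1.0
                active = to_topic
            else:
                active = from_topic
        else:
            active = from_topic
        tokens.append(topics.sample_tokens(active, 1, rng)[0])
        trajectory.append(to_topic if ramp >= 0.5 else from_topic)
        content_count += 1
    return tokens, trajectory


# ---------------------------------------------------------------------------
# Norms, factor measures, accuracy trials, LMM data
# ---------------------------------------------------------------------------

# default planted loadings of the 5 norm columns on 4 latent factors
_DEFAULT_NORM_LOADINGS = np.array(
    [
        #  F1    F2    F3    F4
        [0.9, 0.0, 0.0, 0.0],   # frequency
        [0.8, 0.3, 0.0, 0.0],   # concreteness
        [0.0, 0.9, 0.0, 0.0],   # aoa
        [0.3, 0.0, 0.9, 0.0],   # semantic_diversity
        [0.0, 0.0, 0.0, 0.9],   # phonemic_length
    ]
)
_NORM_COLUMNS = ["frequency", "concreteness", "aoa", "semantic_diversity",
                 "phonemic_length"]
# affine maps from z-scale latents to plausible norm scales
_NORM_SCALES = {
    "frequency": (3.0, 0.8),          # log10 frequency per million, roughly
    "concreteness": (3.2, 0.6),       # 1-5 rating scale
    "aoa": (7.0, 2.0),                # years
    "semantic_diversity": (1.8, 0.3),
    "phonemic_length": (5.0, 1.5),    # phonemes
}


def gen_norms(
    words: list[str] | int,
    planted_loadings: np.ndarray | None = None,
    noise_sd: float = 0.3,
    pos_probs: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Psycholinguistic norms with a planted latent-factor structure.

    ``words`` is a word list or a count (synthetic words are then named
    w000...).  Norm columns are linear combinations of 4 latent factors
    plus Gaussian noise, mapped onto plausible scales; at ``noise_sd=0``
    the column-centred table has exact rank 4.  Returns the table and a
    ground-truth record (latent factors and loadings).
    """
    rng = np.random.default_rng(seed)
    if isinstance(words, int):
        words = [f"w{i:04d}" for i in range(words)]
    L = _DEFAULT_NORM_LOADINGS if planted_loadings is None else np.asarray(
        planted_loadings, dtype=float
    )
    if L.shape != (len(_NORM_COLUMNS), 4):
        raise ValueError("planted loading matrix must be 5 columns x 4 factors")
    n = len(words)
    factors = rng.standard_normal((n, 4))
    latent = factors @ L.T + noise_sd * rng.standard_normal((n, len(_NORM_COLUMNS)))

    pos_probs = pos_probs or {"noun": 0.6, "verb": 0.25, "adj": 0.15}
    pos_levels = list(pos_probs.keys())
    pos = rng.choice(pos_levels, size=n, p=[pos_probs[k] for k in pos_levels])

    data = {"word": [w.lower() for w in words], "pos": pos}
    for j, col in enumerate(_NORM_COLUMNS):
        mu, sd = _NORM_SCALES[col]
        data[col] = mu + sd * latent[:, j]
    df = pd.DataFrame(data)[["word", "pos"] + _NORM_COLUMNS]
    truth = {"loadings": L.tolist(), "noise_sd": noise_sd, "seed": seed,
             "factors": factors}
    return df, truth


def gen_factor_measures(
    n: int = 200,
    blocks: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4, 5), (6, 7), (8,)),
    loading: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Observation x measure matrix with a planted block factor structure.

    Measure j loads ``loading`` on exactly one of 4 factors (its block) and
    0 elsewhere; independent Gaussian noise with SD ``noise_sd`` is added.
    Returns (data, true loadings matrix).
    """
    rng = np.random.default_rng(seed)
    p = max(max(b) for b in blocks) + 1
    L = np.zeros((p, len(blocks)))
    for f, block in enumerate(blocks):
        for j in block:
            L[j, f] = loading
    F = rng.standard_normal((n, len(blocks)))
    X = F @ L.T + noise_sd * rng.standard_normal((n, p))
    return X, L


def gen_accuracy(
    effects: dict[str, float] | None = None,
    n_participants: int = 20,
    n_items: int = 60,
    sd_participant: float = 0.5,
    sd_item: float = 0.5,
    participants: list[str] | None = None,
    groups: list[str] | None = None,
    participant_offsets: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Bernoulli accuracy trials from a 2x2x2 factorial logistic model.

    Participants split evenly into control/patient groups (or are given
    explicitly with their group labels); items split evenly over the
    task x demand cells (both factors therefore vary within participant and
    group varies within item).  Fixed effects are given in log-odds on the
    sum-coded (+/-0.5) scale with factor levels coded alphabetically
    (second level +0.5); unstated terms are zero.  Random intercepts for
    participants and items have the stated SDs; ``participant_offsets``
    adds fixed per-participant ability shifts (log-odds) on top of the
    random intercepts, e.g. to tie task ability to speech severity.
    """
    rng = np.random.default_rng(seed)
    effects = {"intercept": 1.5, **(effects or {})}
    if participants is None:
        half = n_participants // 2
        participants = [f"P{i:03d}" for i in range(n_participants)]
        group = ["control"] * half + ["patient"] * (n_participants - half)
    else:
        if groups is None or len(groups) != len(participants):
            raise ValueError("explicit participants need matching groups")
        group = list(groups)
        n_participants = len(participants)
    items = [f"I{i:03d}" for i in range(n_items)]
    item_task = [("task_a" if i % 2 == 0 else "task_b") for i in range(n_items)]
    item_demand = [("high" if (i // 2) % 2 == 0 else "low") for i in range(n_items)]

    u = rng.normal(0.0, sd_participant, n_participants)
    if participant_offsets:
        u = u + np.array([participant_offsets.get(p, 0.0)
                          for p in participants])
    v = rng.normal(0.0, sd_item, n_items)

    rows = []
    for pi, (pid, g) in enumerate(zip(participants, group)):
        for ii, iid in enumerate(items):
            rows.append((pid, g, iid, item_task[ii], item_demand[ii], pi, ii))
    df = pd.DataFrame(
        rows, columns=["participant", "group", "item", "task", "demand",
                       "_pi", "_ii"]
    )

    def code(col):
        levels = sorted(df[col].unique())
        return np.where(df[col] == levels[1], 0.5, -0.5)

    g, t, dm = code("group"), code("task"), code("demand")
    design = {
        "intercept": np.ones(len(df)), "group": g, "task": t, "demand": dm,
        "group:task": g * t, "group:demand": g * dm, "task:demand": t * dm,
        "group:task:demand": g * t * dm,
    }
    eta = sum(effects.get(k, 0.0) * v_ for k, v_ in design.items())
    eta = eta + u[df["_pi"]] + v[df["_ii"]]
    prob = 1.0 / (1.0 + np.exp(-eta))
    df["correct"] = (rng.random(len(df)) < prob).astype(int)
    df = df.drop(columns=["_pi", "_ii"])
    truth = {"effects": effects, "sd_participant": sd_participant,
             "sd_item": sd_item, "seed": seed}
    return df, truth


def gen_lmm_data(
    n_patients: int = 7,
    n_controls: int = 12,
    n_prompts: int = 6,
    intercept: float = 0.49,
    group_effect: float = -0.14,
    sd_participant: float = 0.06,
    sd_prompt: float = 0.03,
    sd_group_prompt: float = 0.0,
    sd_resid: float = 0.08,
    length_effect: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Response-level coherence scores from the group-comparison LMM's own
    generative model (used for statistical calibration and power checks).

    ``group_effect`` is the patient-minus-control shift; response lengths
    mimic typical word counts (patients somewhat shorter and more
    variable) and by default have no true effect on the score.
    """
    rng = np.random.default_rng(seed)
    rows = []
    prompt_fx = rng.normal(0.0, sd_prompt, n_prompts)
    slope_fx = rng.normal(0.0, sd_group_prompt, n_prompts)
    for role, n_sub, length_mu, length_sd in (
        ("control", n_controls, 135.0, 22.0),
        ("patient", n_patients, 133.0, 38.0),
    ):
        for s in range(n_sub):
            pid = f"{role[0].upper()}{s:02d}"
            b = rng.normal(0.0, sd_participant)
            for q in range(n_prompts):
                is_pat = float(role == "patient")
                length = max(40.0, rng.normal(length_mu, length_sd))
                value = (
                    intercept
                    + group_effect * is_pat
                    + slope_fx[q] * is_pat
                    + b
                    + prompt_fx[q]
                    + length_effect * (length - 134.0)
                    + rng.normal(0.0, sd_resid)
                )
                rows.append((pid, f"prompt{q}", role, length, value))
    return pd.DataFrame(
        rows, columns=["participant", "prompt", "group", "length", "value"]
    )


# ---------------------------------------------------------------------------
# Full synthetic study
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """Everything a full pipeline run consumes, plus ground truth."""

    topics: TopicModel
    corpus: list[list[str]]
    transcripts: list[Transcript]
    metadata: pd.DataFrame            # one row per response
    participants: pd.DataFrame        # one row per participant
    norms: pd.DataFrame
    trials: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def _annotate(
    clean: list[str],
    removal_rate: float,
    topics: TopicModel,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Insert annotated disfluency spans so that the removed fraction of the
    raw token stream is close to ``removal_rate``."""
    if removal_rate <= 0:
        return [(t, "keep") for t in clean]
    n = len(clean)
    m = int(round(removal_rate * n / (1.0 - removal_rate)))
    raw = [(t, "keep") for t in clean]
    while m > 0:
        span = int(min(m, rng.integers(1, 4)))
        pos = int(rng.integers(0, len(raw) + 1))
        kind = ["false_start", "perseveration", "task_comment"][
            int(rng.integers(3))
        ]
        if kind == "perseveration" and pos > 0:
            words = [raw[max(0, pos - span) + i][0] for i in range(span)
                     if max(0, pos - span) + i < pos]
        elif kind == "task_comment":
            phrase = _COMMENT_PHRASES[int(rng.integers(len(_COMMENT_PHRASES)))]
            words = phrase.split()[:span]
        else:
            topic = int(rng.integers(topics.n_topics))
            words = topics.sample_tokens(topic, span, rng)
        if not words:
            continue
        raw[pos:pos] = [(w, kind) for w in words]
        m -= len(words)
    return raw


def make_study(
    seed: int = 0,
    n_controls: int = 12,
    n_patients: int = 7,
    n_prompts: int = 6,
    topic_spec: TopicModelSpec | None = None,
    n_docs: int = 400,
    doc_length: int = 150,
    control_drift: float = 0.05,
    patient_drift_range: tuple[float, float] = (0.25, 0.8),
    patient_transition_len: int = 80,
    control_length: tuple[float, float] = (135.0, 22.0),
    patient_length: tuple[float, float] = (133.0, 38.0),
    control_removal: float = 0.016,
    patient_removal: float = 0.09,
    function_word_rate: float = 0.35,
) -> StudyData:
    """Generate a complete synthetic study.

    Controls: ``n_controls`` speakers x ``n_prompts`` prompts, low drift,
    ~60 s of speech.  Patients: ``n_patients`` speakers x 5-6 prompts with
    drift probabilities spread over ``patient_drift_range`` (ordered by
    severity), shorter responses, slower speech, and a higher fraction of
    annotated disfluencies.  Patient-like impairment is induced entirely
    through drift and length, never by editing vectors post hoc.
    """
    rng = np.random.default_rng(seed)
    topics = build_topics(topic_spec or TopicModelSpec(seed=seed))
    corpus, doc_topics = gen_corpus(
        topics, n_docs=n_docs, doc_length=doc_length,
        seed=int(rng.integers(2**31 - 1)),
    )

    prompt_ids = [f"prompt{j}" for j in range(n_prompts)]
    transcripts: list[Transcript] = []
    meta_rows = []
    part_rows = []
    truth_speakers = {}

    def add_speaker(pid, group, drift, length_mu, length_sd, removal,
                    prompts, age, education, transition_len=200):
        fw_rate = float(np.clip(rng.normal(function_word_rate, 0.03), 0.1, 0.6))
        truth_speakers[pid] = {"group": group, "drift_prob": drift,
                               "function_word_rate": fw_rate,
                               "transition_len": transition_len}
        part_rows.append((pid, group, age, education))
        for j in prompts:
            length = int(max(45, rng.normal(length_mu, length_sd)))
            spec = DriftSpec(
                prompt_topic=j,
                drift_prob=drift,
                switch_style="smooth",
                target_length=length,
                transition_len=transition_len,
                function_word_rate=fw_rate,
                seed=int(rng.integers(2**31 - 1)),
            )
            clean, _ = gen_response(spec, topics)
            raw = _annotate(clean, removal, topics, rng)
            if group == "control":
                duration = 60.0
            else:
                wpm = float(np.clip(rng.normal(46.0, 12.0), 20.0, 90.0))
                duration = len(clean) / wpm * 60.0
            t = Transcript(
                participant_id=pid, prompt_id=prompt_ids[j], group=group,
                raw_tokens=raw, duration_s=round(duration, 1),
            )
            transcripts.append(t)
            meta_rows.append((pid, prompt_ids[j], group, t.duration_s))

    for s in range(n_controls):
        add_speaker(
            f"C{s:02d}", "control", control_drift,
            control_length[0], control_length[1], control_removal,
            range(n_prompts),
            age=int(np.clip(rng.normal(67.0, 4.0), 60, 75)),
            education=int(np.clip(rng.normal(13.5, 2.0), 9, 20)),
        )
    drifts = np.linspace(*patient_drift_range, n_patients)
    for s in range(n_patients):
        n_pr = n_prompts if s % 2 == 0 else n_prompts - 1
        add_speaker(
            f"SA{s + 1}", "patient", float(drifts[s]),
            patient_length[0], patient_length[1], patient_removal,
            range(n_pr),
            age=int(np.clip(rng.normal(63.0, 9.0), 45, 85)),
            education=int(np.clip(rng.normal(13.0, 2.0), 9, 20)),
            transition_len=patient_transition_len,
        )

    norms, norms_truth = gen_norms(
        topics.vocabulary, noise_sd=0.3, seed=int(rng.integers(2**31 - 1))
    )
    # semantic task: patients less accurate, high-demand items harder
    # (demand levels code alphabetically, "low" = +0.5), with each
    # patient's ability tied to their drift severity
    acc_effects = {"intercept": 1.5, "group": -0.6, "demand": 0.9,
                   "group:demand": 0.4}
    speaker_ids = [p[0] for p in part_rows]
    speaker_groups = [p[1] for p in part_rows]
    offsets = {
        pid: -2.0 * (truth_speakers[pid]["drift_prob"] - control_drift)
        for pid in speaker_ids
        if truth_speakers[pid]["group"] == "patient"
    }
    trials, acc_truth = gen_accuracy(
        effects=acc_effects,
        participants=speaker_ids,
        groups=speaker_groups,
        participant_offsets=offsets,
        seed=int(rng.integers(2**31 - 1)),
    )

    metadata = pd.DataFrame(
        meta_rows, columns=["participant_id", "prompt_id", "group", "duration_s"]
    )
    participants = pd.DataFrame(
        part_rows, columns=["participant_id", "group", "age", "education"]
    )
    truth = {
        "seed": seed,
        "speakers": truth_speakers,
        "doc_topics": doc_topics,
        "norms": {k: v for k, v in norms_truth.items() if k != "factors"},
        "accuracy": acc_truth,
    }
    return StudyData(
        topics=topics, corpus=corpus, transcripts=transcripts,
        metadata=metadata, participants=participants, norms=norms,
        trials=trials, ground_truth=truth,
    )


def write_study(study: StudyData, directory: str | Path) -> None:
    """Serialize a study into the on-disk formats the pipeline consumes."""
    directory = Path(directory)
    corpus_dir = directory / "corpus"
    transcript_dir = directory / "transcripts"
    corpus_dir.mkdir(parents=True, exist_ok=True)
    transcript_dir.mkdir(parents=True, exist_ok=True)
    for i, doc in enumerate(study.corpus):
        (corpus_dir / f"doc{i:05d}.txt").write_text(" ".join(doc) + "\n")
    for t in study.transcripts:
        name = f"{t.participant_id}_{t.prompt_id}.txt"
        (transcript_dir / name).write_text(serialize_transcript(t) + "\n")
    study.metadata.to_csv(directory / "metadata.csv", index=False)
    study.participants.to_csv(directory / "participants.csv", index=False)
    study.norms.to_csv(directory / "norms.csv", index=False)
    study.trials.to_csv(directory / "trials.csv", index=False)
    (directory / "ground_truth.json").write_text(
        json.dumps(study.ground_truth, indent=1)
    )
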