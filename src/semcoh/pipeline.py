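"""End-to-end orchestration: space -> transcripts -> coherence -> markers
-> statistics, with serialized interfaces between stages and deterministic,
re-runnable outputs.

Every stage writes tidy CSVs into the run's output directory; reports
round values only at the presentation layer ("mean (sd)" tables mirroring
the usual case-series layout).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coherence as coh
from . import markers as mk
from . import stats as st
from . import transcripts as tr
from .semantic_space import build_space, tokenize

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_corpus_dir",
    "load_transcripts",
    "run_pipeline",
    "report_tables",
    "demographics_summary",
    "group_summary",
]

log = logging.getLogger("semcoh")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (serializable to YAML)."""

    corpus_dir: str = "corpus"
    transcript_dir: str = "transcripts"
    metadata: str = "metadata.csv"
    participants: str | None = "participants.csv"
    norms: str | None = "norms.csv"
    trials: str | None = "trials.csv"
    out_dir: str = "out"
    window: int = 20
    d: int = 100
    weighting: str = "log-entropy"
    lc_style: str = "disjoint"
    pca_factors: int = 4
    reference_group: str = "control"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def load_corpus_dir(directory: str | Path) -> list[list[str]]:
    """Read a directory of UTF-8 text files, one tokenized document each."""
    files = sorted(Path(directory).glob("*.txt"))
    if not files:
        raise PipelineError(f"corpus stage: no .txt documents in {directory}")
    return [tokenize(f.read_text(encoding="utf-8")) for f in files]


def load_transcripts(
    directory: str | Path, metadata: pd.DataFrame
) -> list[tr.Transcript]:
    """Parse one transcript file per metadata row (participant_prompt.txt)."""
    out = []
    for row in metadata.itertuples(index=False):
        path = Path(directory) / f"{row.participant_id}_{row.prompt_id}.txt"
        if not path.exists():
            raise PipelineError(f"transcript stage: missing file {path}")
        duration = getattr(row, "duration_s", None)
        if duration is not None and pd.isna(duration):
            duration = None
        try:
            out.append(
                tr.parse_transcript(
                    path.read_text(encoding="utf-8"),
                    participant_id=str(row.participant_id),
                    prompt_id=str(row.prompt_id),
                    group=str(row.group),
                    duration_s=duration,
                )
            )
        except tr.TranscriptParseError as err:
            raise PipelineError(f"transcript stage: {path}: {err}") from err
    return out


def _fmt_mean_sd(values, decimals: int = 2) -> str:
    """"mean (sd)" with sd blank for groups of one."""
    vals = np.asarray([v for v in values if v is not None and np.isfinite(v)])
    if len(vals) == 0:
        return ""
    mean = round(float(vals.mean()), decimals)
    if len(vals) == 1:
        return f"{mean:.{decimals}f}"
    sd = round(float(vals.std(ddof=1)), decimals)
    return f"{mean:.{decimals}f} ({sd:.{decimals}f})"


def group_summary(
    per_participant: pd.DataFrame, group_col: str = "group"
) -> pd.DataFrame:
    """Group mean and sample SD over participant-level values."""
    rows = []
    numeric = [c for c in per_participant.columns
               if c != group_col and pd.api.types.is_numeric_dtype(
                   per_participant[c])]
    for grp, sub in per_participant.groupby(group_col):
        row = {"group": grp, "n": len(sub)}
        for c in numeric:
            vals = sub[c].dropna()
            row[f"{c}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{c}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def demographics_summary(
    participants: pd.DataFrame, decimals: int = 1
) -> pd.DataFrame:
    """Per-group mean age and education (rounded at the report layer)."""
    out = []
    for grp, sub in participants.groupby("group"):
        rec = {"group": grp, "n": len(sub)}
        for col in ("age", "education"):
            if col in sub.columns:
                rec[f"mean_{col}"] = round(float(sub[col].mean()), decimals)
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# The full run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the output directory.

    Returns the output directory path.  Re-running with an identical config
    (and inputs) reproduces byte-identical CSVs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_stages(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> Path:
    # -- stage 1: semantic space ------------------------------------------
    log.info("stage build-space: corpus=%s d=%d", config.corpus_dir, config.d)
    corpus = load_corpus_dir(config.corpus_dir)
    try:
        space = build_space(corpus, d=config.d, weighting=config.weighting)
    except ValueError as err:
        raise PipelineError(f"build-space stage: {err}") from err

    # -- stage 2: transcripts ---------------------------------------------
    metadata = pd.read_csv(config.metadata)
    transcripts = load_transcripts(config.transcript_dir, metadata)
    resp_rows = []
    for t in transcripts:
        elig = tr.check_length(t, w=config.window)
        resp_rows.append({
            "participant_id": t.participant_id,
            "prompt_id": t.prompt_id,
            "group": t.group,
            "n_raw_tokens": len(t.raw_tokens),
            "n_clean_tokens": elig.n_clean_tokens,
            "removed_fraction": float(t.removed_fraction),
            "gc_eligible": elig.gc_eligible,
            "lc_eligible": elig.lc_eligible,
            "duration_s": t.duration_s,
            "speech_rate_wpm": t.speech_rate_wpm,
        })
    responses = pd.DataFrame(resp_rows)
    responses.to_csv(out / "responses.csv", index=False)

    # -- stage 3: coherence ------------------------------------------------
    log.info("stage coherence: w=%d lc=%s", config.window, config.lc_style)
    by_prompt: dict[str, list[tr.Transcript]] = {}
    for t in transcripts:
        by_prompt.setdefault(t.prompt_id, []).append(t)

    results: list[coh.CoherenceResult] = []
    for prompt_id, ts in sorted(by_prompt.items()):
        controls = [
            t for t in ts
            if t.group == config.reference_group
            and len(t.clean_tokens) >= config.window
        ]
        if not controls:
            raise PipelineError(
                f"coherence stage: no eligible {config.reference_group} "
                f"responses for prompt {prompt_id!r}"
            )
        for t in ts:
            if t.group == config.reference_group and len(controls) > 1:
                # leave-one-out composite when scoring a control speaker
                contributors = [
                    c.clean_tokens for c in controls
                    if c.participant_id != t.participant_id
                ]
            else:
                contributors = [c.clean_tokens for c in controls]
            comp = coh.build_composite(contributors, space, prompt_id)
            results.append(coh.score_response(
                t.clean_tokens, space, comp,
                participant_id=t.participant_id, prompt_id=prompt_id,
                w=config.window, lc_style=config.lc_style,
            ))
    coh_df = pd.DataFrame([{
        "participant_id": r.participant_id,
        "prompt_id": r.prompt_id,
        "group": next(t.group for t in transcripts
                      if t.participant_id == r.participant_id),
        "response_length": r.response_length,
        "n_windows_gc": r.n_windows_gc,
        "n_comparisons_lc": r.n_comparisons_lc,
        "gc": r.gc,
        "lc": r.lc,
    } for r in results]).sort_values(
        ["participant_id", "prompt_id"]).reset_index(drop=True)
    coh_df.to_csv(out / "coherence_responses.csv", index=False)

    participant_coh = coh.aggregate_participant(results).reset_index()
    groups = metadata.drop_duplicates("participant_id")[
        ["participant_id", "group"]]
    participant_coh = participant_coh.merge(groups, on="participant_id")
    participant_coh.to_csv(out / "coherence_participants.csv", index=False)

    # -- stage 4: markers + PCA -------------------------------------------
    pca_scores = None
    if config.norms:
        log.info("stage markers: norms=%s", config.norms)
        norms = mk.load_norms(config.norms)
        fw = mk.load_function_words()
        pos_lookup = dict(zip(norms["word"], norms["pos"]))
        marker_rows = []
        for t in transcripts:
            if not t.clean_tokens:
                continue
            tagged = [(w, pos_lookup.get(w, "function" if w in fw else "x"))
                      for w in t.clean_tokens]
            prof = mk.compute_markers(tagged, norms, fw)
            marker_rows.append({
                "participant_id": t.participant_id,
                "prompt_id": t.prompt_id,
                "group": t.group,
                **prof.as_dict(),
            })
        marker_df = pd.DataFrame(marker_rows)
        marker_df.to_csv(out / "markers_responses.csv", index=False)

        # participant-level measures: 7 markers (per-response then averaged)
        # + GC and LC
        part_markers = marker_df.groupby("participant_id")[
            mk.MARKER_NAMES].mean()
        measures = part_markers.join(
            participant_coh.set_index("participant_id")[["gc", "lc"]]
        )
        measures.to_csv(out / "measures_participants.csv")
        complete = measures.dropna()
        if len(complete) >= config.pca_factors:
            model = mk.fit_pca(complete, k=config.pca_factors)
            model.loadings.to_csv(out / "pca_loadings.csv")
            pca_scores = model.scores.merge(
                groups.set_index("participant_id"), left_index=True,
                right_index=True)
            pca_scores.to_csv(out / "pca_scores.csv")

    # -- stage 5: statistics ----------------------------------------------
    log.info("stage stats")
    model_rows = []
    case_rows = []
    for measure in ("gc", "lc"):
        data = coh_df.rename(columns={
            "participant_id": "participant", "prompt_id": "prompt",
            measure: "value", "response_length": "length"})
        data = data.dropna(subset=["value"])
        if data["group"].nunique() >= 2:
            try:
                res, fit = st.group_comparison(
                    data, reference_group=config.reference_group)
                for r in res:
                    model_rows.append({"measure": measure, **r.__dict__,
                                       "simplifications": "; ".join(
                                           fit.simplifications)})
            except st.FitError as err:
                log.warning("group model for %s failed: %s", measure, err)
            ctrl = data[data["group"] == config.reference_group]
            for pid, case in data[
                    data["group"] != config.reference_group].groupby(
                        "participant"):
                try:
                    cc = st.single_case_test(case, ctrl, measure=measure)
                    case_rows.append(cc.__dict__ | {
                        "simplifications": "; ".join(cc.simplifications)})
                except (st.FitError, ValueError) as err:
                    log.warning("case %s (%s) failed: %s", pid, measure, err)
    if model_rows:
        pd.DataFrame(model_rows).to_csv(out / "group_models.csv", index=False)
    if case_rows:
        pd.DataFrame(case_rows).to_csv(out / "single_cases.csv", index=False)

    if config.trials:
        trials = pd.read_csv(config.trials)
        try:
            acc = st.accuracy_glmm(trials)
            pd.DataFrame([r.__dict__ for r in acc]).to_csv(
                out / "accuracy_model.csv", index=False)
        except (st.SeparationError, st.FitError) as err:
            log.warning("accuracy model failed: %s", err)

        # correlations: semantic-control ability (accuracy on high-demand
        # items) vs coherence and factor scores, over the patient group
        demand_levels = sorted(trials["demand"].unique())
        hard = "high" if "high" in demand_levels else demand_levels[0]
        ability = trials[trials["demand"] == hard].groupby(
            "participant")["correct"].mean()
        patients = participant_coh[
            participant_coh["group"] != config.reference_group
        ].set_index("participant_id")
        corr_rows = []
        measures: dict[str, pd.Series] = {
            "gc": patients["gc"], "lc": patients["lc"]}
        if pca_scores is not None:
            pat_scores = pca_scores[
                pca_scores["group"] != config.reference_group]
            for col in pat_scores.columns:
                if col.startswith("factor"):
                    measures[col] = pat_scores[col]
        for name, series in measures.items():
            joined = pd.concat([series, ability], axis=1,
                               join="inner").dropna()
            if len(joined) < 3:
                continue
            try:
                r, p = st.correlate(joined.iloc[:, 0], joined.iloc[:, 1])
            except ValueError as err:
                log.warning("correlation %s failed: %s", name, err)
                continue
            corr_rows.append({"measure": name, "ability": "high_demand_acc",
                              "r": r, "p": p, "n": len(joined)})
        if corr_rows:
            pd.DataFrame(corr_rows).to_csv(out / "correlations.csv",
                                           index=False)

    # -- stage 6: report ---------------------------------------------------
    if config.participants and Path(config.participants).exists():
        demographics_summary(pd.read_csv(config.participants)).to_csv(
            out / "demographics.csv", index=False)
    report_tables(out)
    log.info("pipeline complete: %s", out)
    return out


def report_tables(out_dir: str | Path) -> str:
    """Render human-readable "mean (sd)" summary tables from a run's CSVs.

    Coherence values are shown to 2 decimals; missing upstream files raise
    a report error naming the file.
    """
    out = Path(out_dir)
    path = out / "coherence_participants.csv"
    if not path.exists():
        raise PipelineError(f"report stage: missing {path}")
    part = pd.read_csv(path)
    lines = ["Participant-level coherence", "=" * 30]
    for grp, sub in part.groupby("group"):
        lines.append(f"{grp} (n={len(sub)}):")
        lines.append(f"  Global coherence  {_fmt_mean_sd(sub['gc'])}")
        lines.append(f"  Local coherence   {_fmt_mean_sd(sub['lc'])}")
        lines.append(
            f"  Response length   {_fmt_mean_sd(sub['mean_length'], 1)}")
    resp_path = out / "responses.csv"
    if resp_path.exists():
        resp = pd.read_csv(resp_path)
        lines += ["", "Transcript editing", "=" * 30]
        for grp, sub in resp.groupby("group"):
            pooled = (sub["n_raw_tokens"] - sub["n_clean_tokens"]).sum() / max(
                sub["n_raw_tokens"].sum(), 1)
            lines.append(f"{grp}: {100 * pooled:.1f}% of words removed")
    models_path = out / "group_models.csv"
    if models_path.exists():
        models = pd.read_csv(models_path)
        lines += ["", "Group comparisons", "=" * 30]
        for row in models[models["term"] == "group"].itertuples(index=False):
            df_txt = f", df = {row.df:.1f}" if pd.notna(row.df) else ""
            lines.append(
                f"{row.measure} group effect: B = {row.estimate:.3f}, "
                f"se = {row.se:.3f}{df_txt}, p = {row.p:.3g}"
            )
    corr_path = out / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        lines += ["", "Correlations with semantic control", "=" * 30]
        for row in corr.itertuples(index=False):
            lines.append(
                f"{row.measure}: r = {row.r:.2f}, p = {row.p:.2g} "
                f"(n = {row.n})"
            )
    demo_path = out / "demographics.csv"
    if demo_path.exists():
        demo = pd.read_csv(demo_path)
        lines += ["", "Demographics", "=" * 30]
        for row in demo.itertuples(index=False):
            extras = []
            if hasattr(row, "mean_age"):
                extras.append(f"mean age {row.mean_age}")
            if hasattr(row, "mean_education"):
                extras.append(f"mean education {row.mean_education}")
            lines.append(f"{row.group} (n={row.n}): " + ", ".join(extras))
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
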