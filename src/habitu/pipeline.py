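"""End-to-end orchestration: sessions -> processed signals -> habituation
features -> leave-one-out classification -> attributions -> individual
habituation responses, with JSON/CSV artifacts and report figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import explain, features, model, signal_prep
from .io import SessionFormatError, read_participant_dir
from .signal_prep import ProcessedSignals
from .synth import Cohort, SyntheticSession

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration; defaults follow the study protocol
    (5-s windows, 32 Hz, alpha = 0.05, PCL-M threshold 36)."""

    label_threshold: int = 36
    alpha: float = 0.05
    equal_var: bool = False
    window_s: float = 5.0
    target_rate_hz: float = 32.0
    model_id: str = "gp"
    search_budget: int = 8
    decision_threshold: float = 0.5
    n_permutations: int = 128  # Shapley sampling budget when > 12 features
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    summary: model.EvaluationSummary
    folds: list[model.FoldResult]
    cohort: features.CohortMatrix
    attributions: list[explain.AttributionVector]
    ranking: explain.GlobalImportance
    responses: list[explain.HabituationResponse]
    regression: explain.ResponseRegression
    excluded: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Feature assembly from sessions


def session_features(
    session: SyntheticSession, *, use_ideal: bool = False, window_s: float = 5.0
) -> features.FeatureVector:
    """Process one synthetic session (raw path or ground-truth fast path)
    and extract its habituation features."""
    if use_ideal or session.recording is None:
        signals: ProcessedSignals = session.ideal
    else:
        signals = signal_prep.process_recording(session.recording)
    events = signal_prep.clean_events(session.events, duration=signals.duration)
    return features.habituation_features(
        signals, events, participant_id=session.profile.participant_id, window_s=window_s
    )


def cohort_matrix(
    cohort: Cohort, *, use_ideal: bool = False, label_threshold: int = 36, window_s: float = 5.0
) -> features.CohortMatrix:
    vectors = [
        session_features(s, use_ideal=use_ideal, window_s=window_s) for s in cohort.sessions
    ]
    pclm = {
        s.profile.participant_id: s.profile.pclm_score for s in cohort.sessions
    }
    return features.assemble_cohort(vectors, pclm, label_threshold=label_threshold)


# ---------------------------------------------------------------------------
# Analysis on an assembled matrix


def analyze(cohort: features.CohortMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Leave-one-out evaluation plus per-fold attributions, global
    importance ranking, habituation responses and the PCL-M regression."""
    cfg = config or RunConfig()
    summary, folds = model.loo_evaluate(
        cohort,
        alpha=cfg.alpha,
        equal_var=cfg.equal_var,
        model_id=cfg.model_id,
        search_budget=cfg.search_budget,
        seed=cfg.seed,
        decision_threshold=cfg.decision_threshold,
    )
    attributions, responses = [], []
    for i, fold in enumerate(folds):
        rng = np.random.default_rng((cfg.seed * 100_003 + i) % 2**31)
        att = explain.attribute(fold, n_permutations=cfg.n_permutations, rng=rng)
        attributions.append(att)
        x_raw = {k: float(fold.x_test_raw_imputed[k]) for k in fold.selected_keys}
        responses.append(
            explain.habituation_response(
                x_raw, att, int(cohort.pclm_scores.loc[fold.held_out_id])
            )
        )
    ranking = explain.global_ranking(attributions)
    regression = explain.response_vs_pclm(responses)
    return PipelineResult(
        summary=summary,
        folds=folds,
        cohort=cohort,
        attributions=attributions,
        ranking=ranking,
        responses=responses,
        regression=regression,
    )


# ---------------------------------------------------------------------------
# Directory-based run


def load_cohort_dir(root: str | Path) -> tuple[dict[str, tuple], dict[str, str]]:
    """Load every participant directory under `root`.

    Returns (loaded, excluded): participants whose directory is unreadable
    or incomplete are excluded with a reason, mirroring real acquisition
    failures, and the run continues if enough remain.
    """
    root = Path(root)
    loaded, excluded = {}, {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            specs, recording, meta = read_participant_dir(sub)
            if "pclm_score" not in meta:
                raise SessionFormatError(f"{sub.name}: meta.json lacks pclm_score")
            loaded[sub.name] = (specs, recording, meta)
        except (SessionFormatError, ValueError) as exc:
            log.warning("excluding participant %s: %s", sub.name, exc)
            excluded[sub.name] = str(exc)
    return loaded, excluded


def run_pipeline(input_dir: str | Path, out_dir: str | Path, config: RunConfig | None = None) -> PipelineResult:
    """Full pipeline over a directory of participant recordings; writes
    summary.json, features/attributions/responses CSVs and report figures."""
    cfg = config or RunConfig()
    loaded, excluded = load_cohort_dir(input_dir)

    vectors, pclm = [], {}
    for pid, (specs, recording, meta) in loaded.items():
        try:
            signals = signal_prep.process_recording(recording)
            events = signal_prep.clean_events(specs, duration=signals.duration)
            vec = features.habituation_features(
                signals, events, participant_id=pid, window_s=cfg.window_s
            )
        except (signal_prep.SignalError, features.WindowError) as exc:
            log.warning("excluding participant %s at preprocessing: %s", pid, exc)
            excluded[pid] = str(exc)
            continue
        vectors.append(vec)
        pclm[pid] = int(meta["pclm_score"])

    cohort = features.assemble_cohort(vectors, pclm, label_threshold=cfg.label_threshold)
    result = analyze(cohort, cfg)
    result.excluded = excluded
    write_artifacts(result, out_dir, cfg)
    return result


# ---------------------------------------------------------------------------
# Artifacts


def write_artifacts(result: PipelineResult, out_dir: str | Path, cfg: RunConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    s = result.summary
    summary = {
        "config": dataclasses.asdict(cfg),
        "n_participants": result.cohort.n,
        "accuracy": s.accuracy,
        "tpr": s.tpr,
        "tnr": s.tnr,
        "auc": s.auc,
        "majority_baseline": s.majority_baseline,
        "confusion": s.confusion,
        "n_selected_mean": s.n_selected_mean,
        "n_selected_sd": s.n_selected_sd,
        "regression": dataclasses.asdict(result.regression),
        "excluded": result.excluded,
        "folds": [
            {
                "held_out_id": f.held_out_id,
                "predicted_prob": f.predicted_prob,
                "predicted_label": bool(f.predicted_label),
                "true_label": bool(f.true_label),
                "n_selected": len(f.selected_keys),
            }
            for f in result.folds
        ],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))

    result.cohort.X.to_csv(out / "features.csv")
    att_rows = [
        {"participant_id": a.participant_id, "feature": k, "shap_value": w}
        for a in result.attributions
        for k, w in a.phi.items()
    ]
    pd.DataFrame(att_rows).to_csv(out / "attributions.csv", index=False)
    pd.DataFrame(
        [
            {"participant_id": r.participant_id, "response": r.value, "pclm_score": r.pclm_score}
            for r in result.responses
        ]
    ).to_csv(out / "responses.csv", index=False)
    write_figures(result, out)


def write_figures(result: PipelineResult, out_dir: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    s = result.summary

    # ROC + confusion matrix
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    fpr, tpr = zip(*s.roc)
    ax1.plot(fpr, tpr, marker="o", label=f"AUC = {s.auc:.2f}")
    ax1.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax1.set_xlabel("False positive rate")
    ax1.set_ylabel("True positive rate")
    ax1.set_title("ROC (LOO fold probabilities)")
    ax1.legend()
    c = s.confusion
    mat = np.array([[c["tn"], c["fp"]], [c["fn"], c["tp"]]])
    ax2.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax2.text(j, i, str(v), ha="center", va="center")
    ax2.set_xticks([0, 1], ["pred non-PTSD", "pred PTSD"])
    ax2.set_yticks([0, 1], ["non-PTSD", "PTSD"])
    ax2.set_title(f"Accuracy {s.accuracy:.1%} (baseline {s.majority_baseline:.1%})")
    fig.tight_layout()
    fig.savefig(out / "roc_confusion.svg")
    plt.close(fig)

    # per-participant attribution bars (first three folds)
    for att in result.attributions[:3]:
        keys = sorted(att.phi, key=lambda k: -abs(att.phi[k]))
        vals = [att.phi[k] for k in keys]
        fig, ax = plt.subplots(figsize=(6, 0.3 * len(keys) + 1.2))
        ax.barh(keys[::-1], vals[::-1], color=["green" if v > 0 else "red" for v in vals[::-1]])
        ax.set_xlabel("Shapley value (toward PTSD if > 0)")
        ax.set_title(f"{att.participant_id}: p(PTSD) = {att.model_output:.2f}")
        fig.tight_layout()
        fig.savefig(out / f"attribution_{att.participant_id}.svg")
        plt.close(fig)

    # global importance
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 8))
    keys = list(result.ranking.per_key)[:20]
    ax1.barh(keys[::-1], [result.ranking.per_key[k] for k in keys][::-1])
    ax1.set_title("Cumulative |SHAP| per event/marker pair")
    markers = list(result.ranking.per_marker)
    ax2.barh(markers[::-1], [result.ranking.per_marker[m] for m in markers][::-1])
    ax2.set_title("Cumulative |SHAP| per physiological marker")
    fig.tight_layout()
    fig.savefig(out / "global_importance.svg")
    plt.close(fig)

    # habituation response vs PCL-M
    fig, ax = plt.subplots(figsize=(5.5, 4))
    x = np.array([r.value for r in result.responses])
    y = np.array([r.pclm_score for r in result.responses])
    ax.scatter(x, y, color="tab:blue")
    xs = np.linspace(x.min(), x.max(), 50)
    reg = result.regression
    ax.plot(xs, reg.slope * xs + reg.intercept, color="tab:orange",
            label=f"slope {reg.slope:.2f}, r = {reg.correlation:.2f}")
    ax.axvline(0, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("Individual habituation response")
    ax.set_ylabel("PCL-M score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "response_vs_pclm.svg")
    plt.close(fig)
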