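"""End-to-end orchestration: preprocess -> detect -> segment -> features ->
select -> train -> evaluate, under one serialisable configuration.

Every stage is also usable on its own; this module only wires them
together, keeps the seeding deterministic, and logs the resolved
configuration of each run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, learning
from .features import FEATURE_NAMES, EntropyConfig, extract_all
from .filters import design_lowpass, design_notch, preprocess
from .prv import DetectorConfig, compute_prv, detect_peaks, segment
from .types import ABPRecord, PRVSegment

__all__ = ["PipelineConfig", "PipelineResult", "records_to_features", "run_pipeline"]

log = logging.getLogger("prvarr")

_TRAINERS = {
    "dt": learning.train_dt,
    "elm": learning.train_elm,
    "bpnn": learning.train_bpnn,
}


@dataclass
class PipelineConfig:
    """Resolved settings of one pipeline run; round-trips through a dict.

    The filter block mirrors the default 250 Hz design (mains notch at
    50 Hz with order 2 and gain 64; moving-average low-pass with first
    zero at fs/4); the learning block mirrors the canonical protocol
    (100-tree forest, 15 of 19 features kept, 80/20 hold-out repeated
    100 times).
    """

    notch_f1: float = 50.0
    notch_N: int = 2
    notch_Q: int = 64
    lowpass_f2: float | None = None  # None -> fs / 4
    lowpass_N: int = 2
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    window_beats: int = 16
    step_beats: int = 1
    ntree: int = 100
    mtry: int | None = None
    k_features: int = 15
    classifier: str = "dt"
    n_hidden: int = 300
    bpnn_layers: tuple[int, ...] = (15, 15)
    bpnn_max_iter: int = 3000
    bpnn_lr: float = 0.1
    bpnn_tol: float = 1e-3
    n_rep: int = 100
    test_frac: float = 0.2
    seed: int = 0
    use_annotations: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["detector"] = dataclasses.asdict(self.detector)
        d["entropy"] = dataclasses.asdict(self.entropy)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("detector"), dict):
            det = dict(d["detector"])
            if "band" in det:
                det["band"] = tuple(det["band"])
            d["detector"] = DetectorConfig(**det)
        if isinstance(d.get("entropy"), dict):
            ent = dict(d["entropy"])
            for key in ("pnn_thresholds", "lf_band", "hf_band"):
                if key in ent:
                    ent[key] = tuple(ent[key])
            d["entropy"] = EntropyConfig(**ent)
        for key in ("bpnn_layers",):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def trainer(self):
        """Bound trainer callable ``(X, y, seed) -> TrainedModel``."""
        kind = self.classifier
        if kind not in _TRAINERS:
            raise ValueError(f"unknown classifier {kind!r}")
        if kind == "dt":
            return lambda X, y, seed=0: learning.train_dt(X, y, seed=seed)
        if kind == "elm":
            return lambda X, y, seed=0: learning.train_elm(
                X, y, n_hidden=self.n_hidden, seed=seed
            )
        return lambda X, y, seed=0: learning.train_bpnn(
            X,
            y,
            layers=self.bpnn_layers,
            max_iter=self.bpnn_max_iter,
            lr=self.bpnn_lr,
            tol=self.bpnn_tol,
            seed=seed,
        )


def records_to_segments(
    records: list[ABPRecord],
    window_beats: int = 16,
    step_beats: int = 1,
    detector: DetectorConfig | None = None,
    config: PipelineConfig | None = None,
    use_annotations: bool = False,
) -> list[PRVSegment]:
    """Preprocess, detect and window each record into labelled segments.

    Records on which detection finds too few beats for one window are
    skipped with a logged reason.
    """
    cfg = config or PipelineConfig()
    detector = detector or cfg.detector
    out: list[PRVSegment] = []
    for i, rec in enumerate(records):
        notch = design_notch(rec.fs, cfg.notch_f1, cfg.notch_N, cfg.notch_Q)
        lowpass = design_lowpass(rec.fs, cfg.lowpass_f2 or rec.fs / 4.0, cfg.lowpass_N)
        clean = preprocess(rec, notch, lowpass)
        beats = detect_peaks(clean, detector, use_annotations=use_annotations)
        rid = rec.meta.get("record_id", f"record-{i}")
        if len(beats) < window_beats + 1:
            log.warning("skipping %s: %d beats detected", rid, len(beats))
            continue
        series = compute_prv(beats, label=rec.meta.get("label"), source=rid)
        out.extend(segment(series, window_beats, step_beats))
    return out


def segments_to_features(
    segments: list[PRVSegment], entropy: EntropyConfig | None = None
) -> pd.DataFrame:
    """Feature matrix: one row per segment, 19 feature columns in canonical
    order plus ``label`` and ``source`` provenance columns."""
    entropy = entropy or EntropyConfig()
    rows = []
    for seg in segments:
        row = extract_all(seg, entropy)
        row["label"] = seg.label
        row["source"] = seg.source
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=[*FEATURE_NAMES, "label", "source"])
    df = pd.DataFrame(rows).reset_index(drop=True)
    if df["label"].notna().all():
        df["label"] = df["label"].astype(int)
    return df


def records_to_features(
    records: list[ABPRecord],
    window_beats: int = 16,
    step_beats: int = 1,
    detector: DetectorConfig | None = None,
    entropy: EntropyConfig | None = None,
    use_annotations: bool = False,
) -> tuple[list[PRVSegment], pd.DataFrame]:
    """Convenience wrapper: records -> (segments, feature matrix)."""
    segs = records_to_segments(
        records,
        window_beats=window_beats,
        step_beats=step_beats,
        detector=detector,
        use_annotations=use_annotations,
    )
    return segs, segments_to_features(segs, entropy)


@dataclass
class PipelineResult:
    """All stage outputs of one full run."""

    config: PipelineConfig
    features: pd.DataFrame
    importance: learning.ImportanceTable
    selected: list[str]
    model: learning.TrainedModel
    report: evaluation.EvalReport


def run_pipeline(records: list[ABPRecord], config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole pipeline on labelled records.

    Requires at least two classes after segmentation.  The final model is
    trained on all segments; the report comes from the repeated hold-out
    protocol.  Deterministic under ``config.seed`` for the dt and elm
    classifiers.
    """
    cfg = config or PipelineConfig()
    log.info("pipeline config: %s", cfg.to_dict())
    segs, feats = records_to_features(
        records,
        window_beats=cfg.window_beats,
        step_beats=cfg.step_beats,
        detector=cfg.detector,
        entropy=cfg.entropy,
        use_annotations=cfg.use_annotations,
    )
    if feats.empty:
        raise ValueError("no usable segments: every record was skipped")
    y = feats["label"].to_numpy()
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least two classes after segmentation")
    X = feats[FEATURE_NAMES]
    rng = np.random.default_rng(cfg.seed)
    imp = learning.rf_importance(
        X, y, ntree=cfg.ntree, mtry=cfg.mtry, seed=int(rng.integers(0, 2**31 - 1))
    )
    selected = learning.select_features(imp, cfg.k_features)
    Xs = X[selected]
    trainer = cfg.trainer()
    report = evaluation.repeated_holdout(
        Xs,
        y,
        trainer,
        n_rep=cfg.n_rep,
        test_frac=cfg.test_frac,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    report.meta["classifier"] = cfg.classifier
    model = trainer(Xs, y, seed=int(rng.integers(0, 2**31 - 1)))
    return PipelineResult(
        config=cfg,
        features=feats,
        importance=imp,
        selected=selected,
        model=model,
        report=report,
    )
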