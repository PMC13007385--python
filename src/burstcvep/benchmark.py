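"""Within-participant / domain-adaptation benchmark driver.

Runs the seven decoding pipelines — TS-LDA, CNN, C-CNN, PS-CNN, GREEN,
C-GREEN, PS-GREEN — under the Within-Participant (WP), Domain-Adaptation
(DA) and pretrain/fine-tune procedures on a cohort of sessions, with the
paper's data hygiene: per-participant standardization fit on training data,
undersampling of training epochs only, spatial preprocessing fit on
calibration/training data only, and a leakage guard asserting that no
target test trial ever enters a training set.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .decoders import CNNClassifier, GreenClassifier, TSLDAClassifier
from .evaluate import decode_trial_from_probs, epoch_metrics
from .preprocess import EpochSet, Standardizer, bandpass_fir, make_split, slice_epochs, undersample
from .spatial import CompletePreprocessor
from .stats import bonferroni, wilcoxon_stouffer

__all__ = ["PIPELINES", "PROCEDURES", "prepare_session", "run_evaluation", "benchmark", "pairwise_stats"]

PIPELINES = ("TS-LDA", "CNN", "C-CNN", "PS-CNN", "GREEN", "C-GREEN", "PS-GREEN")
PROCEDURES = ("WP", "DA", "PRETRAIN_FT")

N_CALIB_TRIALS = 10  # runs 1-2


class LeakageError(RuntimeError):
    """A test trial reached a training set."""


class PreparedSession:
    """Band-passed, epoched session with calibration/test masks."""

    def __init__(self, session, stride: int = 8):
        self.pid = session.participant_id
        self.session = session
        filtered = bandpass_fir(session.eeg, fs=session.fs)
        self.epochs = slice_epochs(session, stride_samples=stride, filtered_eeg=filtered)
        self.stride = stride
        nt = int(round(0.35 * session.fs))
        starts = np.arange(0, session.trial_samples - nt, stride)
        self.codes_at_starts = session.code_set.upsample(session.fs)[:, starts]
        self.calib_mask = self.epochs.trial_index < N_CALIB_TRIALS
        self.test_mask = ~self.calib_mask

    def standardized(self, train_mask: np.ndarray) -> EpochSet:
        """All epochs scaled by the SD of this participant's training part."""
        sc = Standardizer().fit(self.epochs.data[train_mask])
        return self.epochs.with_data(sc.transform(self.epochs.data))


def prepare_session(session, stride: int = 8) -> PreparedSession:
    return PreparedSession(session, stride=stride)


def _decoder(pipeline: str, seed: int, decoder_params: dict | None):
    decoder_params = decoder_params or {}
    base = pipeline.split("-")[-1]  # CNN / GREEN / LDA
    if pipeline == "TS-LDA":
        return TSLDAClassifier(seed=seed, **decoder_params.get("tslda", {}))
    if base == "CNN":
        return CNNClassifier(seed=seed, **decoder_params.get("cnn", {}))
    if base == "GREEN":
        return GreenClassifier(seed=seed, **decoder_params.get("green", {}))
    raise ValueError(f"unknown pipeline {pipeline!r}")


def _scheme(pipeline: str) -> str:
    if pipeline.startswith("C-"):
        return "combined"
    if pipeline.startswith("PS-"):
        return "ps"
    return "small"


def _guard_disjoint(split, test_epochs: EpochSet) -> None:
    test_pairs = {
        (int(p), int(t))
        for p, t in zip(test_epochs.participant_id, test_epochs.trial_index)
    }
    if test_pairs & set(split.train_trials):
        raise LeakageError("test trials present in the training set")


def run_evaluation(
    prepared: dict,
    pipeline: str,
    procedure: str,
    target_id: int,
    source_id: int | None = None,
    seed: int = 0,
    decoder_params: dict | None = None,
    window: int = 30,
    use_probabilities: bool = False,
) -> dict:
    """One (pipeline, procedure, target[, source]) cell of the benchmark."""
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}")
    procedure = procedure.upper()
    split = make_split(procedure, target_id, source_id)
    tgt = prepared[target_id]

    tgt_std = tgt.standardized(tgt.calib_mask)
    tgt_calib = tgt_std.select(tgt.calib_mask)
    tgt_test = tgt_std.select(tgt.test_mask)
    _guard_disjoint(split, tgt_test)

    src_all = src_calib = None
    if procedure != "WP":
        src = prepared[source_id]
        src_std = src.standardized(np.ones(len(src.epochs), dtype=bool))
        src_all = src_std
        src_calib = src_std.select(src.calib_mask)

    scheme = _scheme(pipeline)
    t0 = time.perf_counter()

    # ---- assemble feature spaces per scheme ------------------------------
    if pipeline == "TS-LDA" or scheme == "small":
        train_sets = [tgt_calib] if procedure == "WP" else [src_all, tgt_calib]
        test_feats = tgt_test
        pretrain_X = None if procedure != "PRETRAIN_FT" else src_all
    elif scheme == "combined":
        # preprocessing fit jointly with the model on its training set
        fit_on = tgt_calib if procedure == "WP" else (
            src_all if procedure == "PRETRAIN_FT"
            else EpochSet.concatenate([src_all, tgt_calib])
        )
        pre = CompletePreprocessor().fit(fit_on.data, fit_on.labels)
        test_feats = tgt_test.with_data(pre.transform(tgt_test.data), "SUPER")
        train_sets = [tgt_calib.with_data(pre.transform(tgt_calib.data), "SUPER")]
        if procedure != "WP":
            train_sets.insert(0, src_all.with_data(pre.transform(src_all.data), "SUPER"))
        pretrain_X = None if procedure != "PRETRAIN_FT" else train_sets[0]
    else:  # participant-specific
        pre_t = CompletePreprocessor().fit(tgt_calib.data, tgt_calib.labels)
        test_feats = tgt_test.with_data(pre_t.transform(tgt_test.data), "SUPER")
        train_sets = [tgt_calib.with_data(pre_t.transform(tgt_calib.data), "SUPER")]
        if procedure != "WP":
            pre_s = CompletePreprocessor().fit(src_calib.data, src_calib.labels)
            train_sets.insert(0, src_all.with_data(pre_s.transform(src_all.data), "SUPER"))
        pretrain_X = None if procedure != "PRETRAIN_FT" else train_sets[0]

    clf = _decoder(pipeline, seed, decoder_params)

    # ---- train -----------------------------------------------------------
    rng_seed = seed + 17 * target_id + (0 if source_id is None else 10007 * source_id)
    if procedure == "PRETRAIN_FT" and pipeline != "TS-LDA":
        pre_train = undersample(pretrain_X, seed=rng_seed)
        clf.fit(pre_train.data, pre_train.labels)
        ft = undersample(train_sets[-1], seed=rng_seed + 1)
        clf.finetune(ft.data, ft.labels)
    else:
        # TS-LDA's pretrain/fine-tune analogue is a refit on the pooled data
        train = undersample(EpochSet.concatenate(train_sets), seed=rng_seed)
        clf.fit(train.data, train.labels)
    train_time = time.perf_counter() - t0

    # ---- test ------------------------------------------------------------
    t0 = time.perf_counter()
    probs = clf.predict_proba(test_feats.data)[:, 1]
    y_pred = (probs >= 0.5).astype(int)
    metrics = epoch_metrics(test_feats.labels, y_pred)

    trial_results = []
    for trial in np.unique(test_feats.trial_index):
        m = test_feats.trial_index == trial
        order = np.argsort(test_feats.onset_sample[m])
        true_code = int(test_feats.class_index[m][0])
        trial_results.append(
            decode_trial_from_probs(
                probs[m][order], tgt.codes_at_starts, true_code=true_code,
                trial_id=int(trial), window=window,
                use_probabilities=use_probabilities,
            )
        )
    predict_time = time.perf_counter() - t0

    return {
        "pipeline": pipeline,
        "procedure": procedure,
        "target": target_id,
        "source": source_id,
        "balanced_accuracy": metrics["balanced_accuracy"],
        "recall": metrics["recall"],
        "f1": metrics["f1"],
        "trial_accuracy": float(np.mean([r.correct for r in trial_results])),
        "mean_stop_epoch": float(np.mean([r.stop_epoch for r in trial_results])),
        "train_time": train_time,
        "predict_time": predict_time,
    }


def benchmark(
    sessions,
    pipelines=("TS-LDA",),
    procedures=("WP",),
    stride: int = 8,
    seed: int = 0,
    decoder_params: dict | None = None,
    da_pairs: list | None = None,
    window: int = 30,
) -> pd.DataFrame:
    """Evaluate pipelines x procedures over a cohort.

    WP gives one score per target participant; DA / pretrain-fine-tune give
    one score per ordered (source, target) pair — all S(S-1) pairs unless
    ``da_pairs`` lists a subset.  Returns one row per evaluation.
    """
    prepared = {s.participant_id: prepare_session(s, stride=stride) for s in sessions}
    ids = sorted(prepared)
    rows = []
    for procedure in procedures:
        procedure = procedure.upper()
        if procedure == "WP":
            cells = [(t, None) for t in ids]
        else:
            if len(ids) < 2:
                raise ValueError("domain adaptation needs at least 2 participants")
            cells = da_pairs if da_pairs is not None else [
                (t, s) for t in ids for s in ids if s != t
            ]
        for pipeline in pipelines:
            for target, source in cells:
                rows.append(
                    run_evaluation(
                        prepared, pipeline, procedure, target, source,
                        seed=seed, decoder_params=decoder_params, window=window,
                    )
                )
    return pd.DataFrame(rows)


def pairwise_stats(report: pd.DataFrame, metric: str = "balanced_accuracy") -> pd.DataFrame:
    """All pairwise pipeline comparisons per procedure, Bonferroni-corrected.

    Scores are aggregated per target participant (mean over sources in DA)
    and compared pairwise with the Wilcoxon/Stouffer/SMD machinery; the
    Bonferroni family is all pairwise comparisons within the call.
    """
    out = []
    for proc, sub in report.groupby("procedure"):
        table = sub.groupby(["pipeline", "target"])[metric].mean().unstack()
        pipes = list(table.index)
        for i, a in enumerate(pipes):
            for b in pipes[i + 1 :]:
                res = wilcoxon_stouffer(table.loc[a].values, table.loc[b].values)
                out.append({
                    "procedure": proc, "pipeline_a": a, "pipeline_b": b,
                    "metric": metric, "wilcoxon_p": float(np.atleast_1d(res.wilcoxon_p)[0]),
                    "stouffer_z": res.stouffer_z, "stouffer_p": res.stouffer_p,
                    "smd": res.smd,
                })
    df = pd.DataFrame(out)
    if len(df):
        df["p_bonferroni"] = bonferroni(df["stouffer_p"].values)
    return df
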