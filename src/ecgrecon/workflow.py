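"""End-to-end reconstruction experiments and method comparison.

The protocol: band-limit the record (0.67-150 Hz zero-phase), split it into
a training prefix (default 16 s) and a test remainder, fit each requested
reconstruction method on the prefix only, reconstruct the target leads on
the test remainder, and score every (lead, method) pair with the five
figures of merit.  Methods are compared against a control (simple linear
regression by default) with pooled two-sided Wilcoxon rank-sum tests per
figure of merit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ann import LmConfig, MlpLeadRegression
from .exceptions import ConfigError, SignalLengthError
from .io import STANDARD_12_LEAD_NAMES, EcgRecord
from .linear import LinearLeadRegression, SegmentedLinearRegression
from .metrics import FOM_NAMES, fom_report, reports_to_frame, wilcoxon_rank_sum
from .preprocess import FilterSpec, bandpass_filter
from .segmentation import SegmentationParams, detect_r_peaks, p_wave_windows

__all__ = [
    "ExperimentConfig",
    "METHOD_NAMES",
    "run_experiment",
    "compare_methods",
    "sweep_hidden",
    "plot_fom_boxplots",
]

logger = logging.getLogger(__name__)

METHOD_NAMES = ("linear", "segmented", "ann_per_lead", "ann_all_leads")


@dataclass
class ExperimentConfig:
    """Everything that defines one reconstruction experiment."""

    input_leads: tuple[str, str, str] = ("ES", "AS", "AI")
    target_leads: tuple[str, ...] = tuple(STANDARD_12_LEAD_NAMES)
    train_seconds: float = 16.0
    methods: tuple[str, ...] = METHOD_NAMES
    n_hidden: int = 10
    filter_spec: FilterSpec | None = field(default_factory=FilterSpec)
    segmentation: SegmentationParams = field(
        default_factory=SegmentationParams)
    lm: LmConfig = field(default_factory=LmConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.input_leads) != 3:
            raise ConfigError("exactly 3 input leads are required")
        unknown = set(self.methods) - set(METHOD_NAMES)
        if unknown:
            raise ConfigError(f"unknown method(s): {sorted(unknown)}")


def _split_record(record: EcgRecord, cfg: ExperimentConfig):
    missing = [name for name in (*cfg.input_leads, *cfg.target_leads)
               if name not in record.channels]
    if missing:
        raise ConfigError(f"record lacks configured lead(s): {missing}")
    n_train = int(round(cfg.train_seconds * record.sampling_rate))
    if not (0 < n_train < record.n_samples):
        raise SignalLengthError(
            f"training prefix of {n_train} samples does not fit a record "
            f"of {record.n_samples} samples"
        )
    x = record.subset(cfg.input_leads)
    y = record.subset(cfg.target_leads)
    return (x[:, :n_train], y[:, :n_train]), (x[:, n_train:], y[:, n_train:])


def _fit_predict(method: str, train, test, record, cfg: ExperimentConfig):
    (x_tr, y_tr), (x_te, _) = train, test
    names = dict(input_names=list(cfg.input_leads),
                 target_names=list(cfg.target_leads))
    if method == "linear":
        res = LinearLeadRegression(x_tr, y_tr, **names).fit()
        logger.info("linear: per-lead train SSE %s", res.train_sse)
        return res.predict(x_te)
    if method == "segmented":
        fs = record.sampling_rate
        # R peaks and windows are computed independently on the train and
        # test portions (the detector lead is the first input lead)
        win_tr = p_wave_windows(
            detect_r_peaks(x_tr[0], fs), cfg.segmentation, x_tr.shape[1])
        res = SegmentedLinearRegression(
            x_tr, y_tr, win_tr, params=cfg.segmentation, **names).fit()
        win_te = p_wave_windows(
            detect_r_peaks(x_te[0], fs), cfg.segmentation, x_te.shape[1])
        return res.predict(x_te, win_te)
    strategy = "per_lead" if method == "ann_per_lead" else "all_leads"
    res = MlpLeadRegression(
        x_tr, y_tr, strategy=strategy, n_hidden=cfg.n_hidden,
        config=cfg.lm, **names).fit(seed=cfg.seed)
    for label, hist in zip(
            cfg.target_leads if strategy == "per_lead" else ["all"],
            res.loss_histories):
        logger.info("%s[%s]: final training SSE %.6e (%d epochs)",
                    method, label, hist[-1], len(hist) - 1)
    return res.predict(x_te)


def run_experiment(record: EcgRecord,
                   cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    """Run the train/test protocol; one FoM row per target lead x method.

    Models see only the training prefix (first ``train_seconds``); all
    figures of merit are computed on the test remainder.  Deterministic for
    a fixed ``cfg.seed``.
    """
    cfg = cfg or ExperimentConfig()
    if cfg.filter_spec is not None:
        record = bandpass_filter(record, cfg.filter_spec)
    train, test = _split_record(record, cfg)
    _, y_te = test
    reports = []
    for method in cfg.methods:
        recon = _fit_predict(method, train, test, record, cfg)
        for k, lead in enumerate(cfg.target_leads):
            reports.append(fom_report(y_te[k], recon[k], lead_name=lead,
                                      method_name=method))
    return reports_to_frame(reports)


def compare_methods(fom_table: pd.DataFrame,
                    control: str = "linear") -> pd.DataFrame:
    """Pooled Wilcoxon rank-sum p-values: control vs. every other method.

    Rows are the five figures of merit, columns the non-control methods;
    each cell pools that FoM's per-lead values across the table.
    """
    methods = list(dict.fromkeys(fom_table["method"]))
    if control not in methods:
        raise ConfigError(f"control method {control!r} not in table")
    if len(methods) < 2:
        raise ConfigError("need at least two methods to compare")
    ctrl = fom_table[fom_table["method"] == control]
    out = {}
    for method in methods:
        if method == control:
            continue
        other = fom_table[fom_table["method"] == method]
        out[method] = [
            wilcoxon_rank_sum(ctrl[fom].to_numpy(), other[fom].to_numpy())
            for fom in FOM_NAMES
        ]
    return pd.DataFrame(out, index=FOM_NAMES)


def sweep_hidden(record: EcgRecord, cfg: ExperimentConfig | None = None,
                 grid=(2, 5, 10, 15, 20),
                 method: str = "ann_all_leads") -> pd.DataFrame:
    """Hidden-layer-size sweep: mean test FoMs per candidate size."""
    cfg = cfg or ExperimentConfig()
    rows = []
    for h in grid:
        sub = ExperimentConfig(
            input_leads=cfg.input_leads, target_leads=cfg.target_leads,
            train_seconds=cfg.train_seconds, methods=(method,),
            n_hidden=h, filter_spec=cfg.filter_spec,
            segmentation=cfg.segmentation, lm=cfg.lm, seed=cfg.seed)
        table = run_experiment(record, sub)
        row = {"n_hidden": h}
        row.update(table[FOM_NAMES].mean().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_fom_boxplots(fom_table: pd.DataFrame, path=None):
    """One box per method per figure of merit (five panels)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = list(dict.fromkeys(fom_table["method"]))
    fig, axes = plt.subplots(1, len(FOM_NAMES), figsize=(16, 4))
    for ax, fom in zip(np.atleast_1d(axes), FOM_NAMES):
        data = [fom_table.loc[fom_table["method"] == m, fom] for m in methods]
        ax.boxplot(data, tick_labels=methods)
        ax.set_title(fom)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
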