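"""End-to-end orchestration: simulate → eGFR → label → preprocess → screen
→ select → train → evaluate → concordance, with a reproducible manifest.

Every stage writes its artifact under the run's output directory; the
manifest records the resolved configuration, the declared inputs/outputs of
each stage and a SHA-256 checksum of every artifact, so a rerun with the
same config and seed can be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import panel as pnl
from . import preprocess as pp
from . import screen as scr
from .egfr import EgfrMethod, compute_egfr
from .simulate import GroundTruth, SimulationConfig, simulate_cohort, write_cohort
from .trajectory import KidneyLabel, fit_egfr_slope, label_discovery, label_validation

__all__ = [
    "RunConfig",
    "run_pipeline",
    "add_egfr_columns",
    "compute_labels",
    "PipelineError",
]

ALL_METHODS = [m.value for m in EgfrMethod]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for machine consumption."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.record = {"stage": stage, "error": message}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Thresholds default to the pipeline's standard constants: 30% detection
    frequency, nominal p < .05, concordance in ≥3 of 4 equations, Spearman
    p < .1 for the agreement regression, SVM C = 256 / gamma = 2e-5, and
    model development on the EKFC cystatin labeling.
    """

    outdir: str = "nephropep_run"
    seed: int = 0
    # inputs: either paths to existing files, or a simulation block
    visits_path: Optional[str] = None
    matrix_path: Optional[str] = None
    standards_path: Optional[str] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # analysis settings
    methods: List[str] = field(default_factory=lambda: list(ALL_METHODS))
    window: str = "full_period"
    rule_set: str = "discovery"  # or 'validation'
    validation_cohort_rule: str = "loss_lt_10"
    training_method: str = EgfrMethod.EKFC_CYS.value
    frequency_threshold: float = 0.30
    p_threshold: float = 0.05
    min_methods: int = 3
    rho_p_threshold: float = 0.1
    svm_c: float = 256.0
    svm_gamma: float = 2e-5
    run_take_one_out: bool = True

    def __post_init__(self):
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown eGFR method(s) {bad}; valid: {ALL_METHODS}")
        if self.training_method not in self.methods:
            raise ValueError("training_method must be one of the configured methods")
        if not 0.0 <= self.frequency_threshold <= 1.0:
            raise ValueError("frequency_threshold must be in [0, 1]")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 1 <= self.min_methods <= 4:
            raise ValueError("min_methods must be in 1..4")
        if self.window not in ("full_period", "between_visits"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.rule_set not in ("discovery", "validation"):
            raise ValueError(f"unknown rule_set {self.rule_set!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# stage helpers (also used directly by the CLI subcommands)
# ---------------------------------------------------------------------------

def add_egfr_columns(visits: pd.DataFrame, methods: Sequence[str]) -> pd.DataFrame:
    """Append one ``egfr_<METHOD>`` column per requested equation.

    Age at each visit is ``age_baseline + time_years``; serum creatinine and
    cystatin C come from the ``scr_mg_dl`` / ``scys_mg_l`` columns.
    """
    out = visits.copy()
    age = visits["age_baseline"].to_numpy(float) + visits["time_years"].to_numpy(float)
    sex = visits["sex"].to_numpy()
    for m in methods:
        method = EgfrMethod(m)
        out[f"egfr_{m}"] = compute_egfr(
            age,
            sex,
            method,
            scr=visits["scr_mg_dl"].to_numpy(float),
            scys=visits["scys_mg_l"].to_numpy(float),
        )
    return out


def compute_labels(
    visits_egfr: pd.DataFrame,
    methods: Sequence[str],
    window: str = "full_period",
    rule_set: str = "discovery",
    validation_cohort_rule: str = "loss_lt_10",
) -> pd.DataFrame:
    """Per-patient percentage slopes and kidney-function labels per method.

    Returns a tidy frame (patient_id, method, window, pct_slope, label).
    Under the validation rule set the label comes from the absolute eGFR
    rules; the percentage slope is still reported for reference.
    """
    rows = []
    for pid, grp in visits_egfr.sort_values("time_years").groupby("patient_id", sort=True):
        t = grp["time_years"].to_numpy(float)
        for m in methods:
            egfr = grp[f"egfr_{m}"].to_numpy(float)
            fit = fit_egfr_slope(t, egfr, window=window)
            pct = fit.pct_slope
            if rule_set == "discovery":
                label = label_discovery(pct)
            else:
                label = label_validation(egfr, validation_cohort_rule)
            rows.append((pid, m, window, pct, label.value))
    return pd.DataFrame(rows, columns=["patient_id", "method", "window", "pct_slope", "label"])


def _label_series(labels: pd.DataFrame, method: str) -> pd.Series:
    sub = labels[labels["method"] == method]
    return pd.Series(sub["label"].to_numpy(), index=sub["patient_id"].to_numpy())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (pd.Series,)):
        return x.to_dict()
    if dataclasses.is_dataclass(x):
        return dataclasses.asdict(x)
    if isinstance(x, tuple):
        return list(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    Any stage failure raises :class:`PipelineError` naming the stage. With a
    fixed config (and seed, when simulating) the artifacts are
    bit-identical across runs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": []}

    def record(stage: str, inputs: List[str], outputs: Dict[str, Path]):
        manifest["stages"].append(
            {
                "stage": stage,
                "inputs": sorted(inputs),
                "outputs": {k: str(p) for k, p in outputs.items()},
                "checksums": {k: _sha256(p) for k, p in sorted(outputs.items())},
            }
        )

    # -- stage 1: obtain inputs ---------------------------------------------
    truth: Optional[GroundTruth] = None
    try:
        if config.visits_path and config.matrix_path:
            visits = pd.read_csv(config.visits_path)
            matrix = pd.read_csv(config.matrix_path, sep="\t", index_col=0)
            record("input", [config.visits_path, config.matrix_path], {})
        else:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            visits, matrix, truth = simulate_cohort(sim_cfg)
            paths = write_cohort(visits, matrix, truth, outdir / "cohort")
            record("simulate", [], paths)
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001
                raise PipelineError(name, str(e)) from e
        return deco

    # -- stage 2: eGFR -------------------------------------------------------
    @stage("egfr")
    def visits_egfr():
        out = add_egfr_columns(visits, config.methods)
        p = outdir / "visits_egfr.csv"
        out.to_csv(p, index=False, float_format="%.10g")
        record("egfr", ["visits"], {"visits_egfr": p})
        return out

    # -- stage 3: labeling ---------------------------------------------------
    @stage("label")
    def labels():
        out = compute_labels(
            visits_egfr,
            config.methods,
            window=config.window,
            rule_set=config.rule_set,
            validation_cohort_rule=config.validation_cohort_rule,
        )
        p = outdir / "labels.csv"
        out.to_csv(p, index=False, float_format="%.10g")
        record("label", ["visits_egfr"], {"labels": p})
        return out

    # -- stage 4: preprocess -------------------------------------------------
    @stage("preprocess")
    def preprocessed():
        mat = matrix
        outputs: Dict[str, Path] = {}
        if config.standards_path:
            standards = [
                s.strip()
                for s in Path(config.standards_path).read_text().splitlines()
                if s.strip()
            ]
            mat, model = pp.normalize(mat, standards)
            sp = outdir / "normalization.json"
            _write_json(
                sp,
                {
                    "standards": model.standards,
                    "scale_factors": model.scale_factors,
                    "skipped_samples": model.skipped_samples,
                },
            )
            outputs["normalization"] = sp
        p = outdir / "matrix_preprocessed.tsv"
        mat.to_csv(p, sep="\t", float_format="%.10g")
        outputs["matrix"] = p
        record("preprocess", ["matrix"], outputs)
        return mat

    # -- stage 5: per-method screens ----------------------------------------
    screens_slopes: list = [None]

    @stage("screen")
    def screens():
        out: Dict[str, pd.DataFrame] = {}
        outputs: Dict[str, Path] = {}
        slopes_by_method: Dict[str, pd.Series] = {}
        for m in config.methods:
            lab = _label_series(labels, m).reindex(preprocessed.index)
            keep = lab.isin([KidneyLabel.UNCONTROLLED.value, KidneyLabel.CONTROLLED.value])
            sub = preprocessed.loc[keep.to_numpy()]
            lab = lab[keep]
            kept_peps = pp.frequency_filter(sub, lab, config.frequency_threshold)
            stats_df = scr.wilcoxon_screen(sub[kept_peps], lab)
            slopes = (
                labels[labels["method"] == m].set_index("patient_id")["pct_slope"]
            ).reindex(sub.index)
            rho_df = scr.spearman_slope_correlation(sub[kept_peps], slopes)
            stats_df = stats_df.join(rho_df)
            out[m] = stats_df
            slopes_by_method[m] = slopes
            p = outdir / f"stats_{m}.tsv"
            stats_df.to_csv(p, sep="\t", float_format="%.10g")
            outputs[m] = p
        record("screen", ["matrix_preprocessed", "labels"], outputs)
        screens_slopes[0] = slopes_by_method
        return out

    # -- stage 6: concordance selection --------------------------------------
    @stage("select")
    def selected():
        crit = pnl.ConcordanceCriteria(
            min_methods=config.min_methods, p_threshold=config.p_threshold
        )
        sel = pnl.select_concordant_panel(screens, crit)
        p = outdir / "panel.json"
        _write_json(p, {"criteria": dataclasses.asdict(crit), "peptides": sel})
        record("select", ["stats"], {"panel": p})
        return sel

    # -- stage 7: SVM training -----------------------------------------------
    train_ctx: list = [None]

    @stage("train")
    def model():
        if len(selected) < 2:
            raise ValueError(
                f"concordance selection kept {len(selected)} peptide(s); "
                "cannot train a panel SVM"
            )
        lab = _label_series(labels, config.training_method).reindex(preprocessed.index)
        keep = lab.isin([KidneyLabel.UNCONTROLLED.value, KidneyLabel.CONTROLLED.value])
        sub = preprocessed.loc[keep.to_numpy()]
        lab = lab[keep]
        if config.run_take_one_out:
            mdl = pnl.take_one_out_optimize(sub, lab, selected, config.svm_c, config.svm_gamma)
        else:
            mdl = pnl.train_svm_panel(sub, lab, selected, config.svm_c, config.svm_gamma)
            mdl.loo_auc = pnl.loo_auc(sub, lab, selected, config.svm_c, config.svm_gamma)
        p = outdir / "model.json"
        _write_json(p, mdl.to_dict())
        record("train", ["matrix_preprocessed", "labels", "panel"], {"model": p})
        train_ctx[0] = (sub, lab)
        return mdl

    # -- stage 8: ROC evaluation ---------------------------------------------
    @stage("evaluate")
    def roc():
        sub, lab = train_ctx[0]
        y = (lab == KidneyLabel.UNCONTROLLED.value).to_numpy().astype(int)
        log_X = np.log1p(sub[model.peptides].to_numpy(float))
        scores = pnl.loo_scores(log_X, y, model.C, model.gamma)
        res = ev.roc_auc(scores, y)
        p = outdir / "roc.json"
        _write_json(p, dataclasses.asdict(res))
        record("evaluate", ["model", "matrix_preprocessed", "labels"], {"roc": p})
        return res

    # -- stage 9: concordance report -----------------------------------------
    @stage("concord")
    def concordance():
        by_method = {m: _label_series(labels, m) for m in config.methods}
        conc = ev.label_overlap(by_method)
        venn = {
            lbl: {"|".join(k): v for k, v in cells.items()}
            for lbl, cells in conc.venn_counts.items()
        }
        payload = dataclasses.asdict(conc)
        payload["venn_counts"] = venn
        slopes = screens_slopes[0]
        pairs = {}
        for i, a in enumerate(config.methods):
            for b in config.methods[i + 1:]:
                both = pd.concat([slopes[a], slopes[b]], axis=1, keys=[a, b]).dropna()
                r, pv = ev.baseline_slope_correlation(both[a], both[b])
                pairs[f"{a}|{b}"] = {"pearson_r": r, "p": pv}
        payload["pct_slope_correlations"] = pairs
        agreement = {}
        for i, a in enumerate(config.methods):
            for b in config.methods[i + 1:]:
                try:
                    agreement[f"{a}|{b}"] = scr.method_agreement_regression(
                        screens[a], screens[b], config.rho_p_threshold
                    )
                except ValueError:
                    agreement[f"{a}|{b}"] = None  # too few peptides pass the cut
        payload["rho_agreement_r2"] = agreement
        p = outdir / "concordance.json"
        _write_json(p, payload)
        record("concord", ["labels"], {"concordance": p})
        return conc

    manifest["summary"] = {
        "n_patients": int(visits["patient_id"].nunique()),
        "n_peptides": int(matrix.shape[1]),
        "panel_size_selected": len(selected),
        "panel_size_final": len(model.peptides),
        "loo_auc": model.loo_auc,
        "roc": dataclasses.asdict(roc),
        "overlap_proportion": concordance.proportion,
    }
    mp = outdir / "manifest.json"
    _write_json(mp, manifest)
    return manifest
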