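"""End-to-end orchestration: simulate → ΔΔCt → panel score → ELISA → classify.

One :class:`RunConfig` (plus a global seed) fully determines a run.  The
classification stage consumes a marker table assembled from the qPCR stage
(sham-independent relative expressions 2^−ΔCt of the 8 panel transcripts —
fold changes would need a paired sham sample that a field-triage scenario
lacks) joined with the sham-relative pCHK2-thr68 protein readout of the
same blood samples, giving the default 2 draws x 5 donors x 4 classes = 40
observations.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as cl
from . import elisa as el
from . import qpcr, score
from . import simulate as sim
from .design import CLASS_ORDER, MARKERS_9, PANEL_8, PROTEIN_MARKER

__all__ = ["RunConfig", "RunReport", "run_full_pipeline", "validate_config",
           "assemble_marker_dataset", "load_run_config"]

log = logging.getLogger("radpanel")


@dataclass
class RunConfig:
    """Stage configurations plus thresholds for one reproducible run."""

    generator: sim.GeneratorConfig = field(default_factory=sim.default_config)
    elisa: sim.ElisaGeneratorConfig = field(default_factory=sim.default_elisa_config)
    matrix: sim.MatrixGeneratorConfig = field(default_factory=sim.default_matrix_config)
    classifier: cl.ClassifierConfig = field(default_factory=cl.ClassifierConfig)
    reference_gene: str = "ACTB"
    stability_threshold: float = 0.3
    p_threshold: float = 0.05
    fold_threshold: float = 2.0
    seed: int = 0

    def reseeded(self) -> "RunConfig":
        """Derive per-stage seeds from the global seed (all below 2^31)."""
        child = np.random.default_rng(self.seed).integers(0, 2 ** 31 - 1, 4)
        return dataclasses.replace(
            self,
            generator=dataclasses.replace(self.generator, seed=int(child[0])),
            elisa=dataclasses.replace(self.elisa, seed=int(child[1])),
            matrix=dataclasses.replace(self.matrix, seed=int(child[2])),
            classifier=dataclasses.replace(self.classifier, seed=int(child[3])),
        )


@dataclass
class RunReport:
    fold_changes: pd.DataFrame
    panel: qpcr.PanelSelection
    score_summary: pd.DataFrame
    score_pairwise: pd.DataFrame
    elisa_folds: pd.DataFrame
    elisa_tests: pd.DataFrame
    marker_data: pd.DataFrame
    marker_order: cl.MarkerOrder
    accuracy_curve: pd.DataFrame
    screening: cl.ScreeningReport
    provenance: dict


def validate_config(config: RunConfig) -> list[str]:
    """All configuration problems; an empty list means runnable."""
    problems: list[str] = []
    g = config.generator
    for name in ("donor_sd", "draw_sd", "tech_sd", "response_sd"):
        if getattr(g, name) < 0:
            problems.append(f"{name} must be >= 0")
    for name in ("n_donors", "n_draws", "n_replicates"):
        if getattr(g, name) < 1:
            problems.append(f"{name} must be >= 1")
    if config.classifier.k_neighbors % 2 == 0:
        problems.append("k must be odd")
    known = {p.gene for p in g.genes}
    if config.reference_gene not in known:
        problems.append(f"unknown reference gene {config.reference_gene!r}")
    if not set(PANEL_8) <= known:
        problems.append("generator lacks panel genes")
    if config.stability_threshold <= 0:
        problems.append("stability threshold must be > 0")
    if not 0 < config.p_threshold < 1:
        problems.append("p threshold must be in (0, 1)")
    if config.fold_threshold <= 1:
        problems.append("fold threshold must be > 1")
    if g.n_draws * g.n_donors * 4 < 2 * config.classifier.n_folds:
        problems.append("too few observations for the fold count")
    return problems


def assemble_marker_dataset(
    rel_table: pd.DataFrame, elisa_ds: pd.DataFrame, protein: str = PROTEIN_MARKER
) -> tuple[pd.DataFrame, pd.Series]:
    """Join transcript relative expressions with the sham-relative protein.

    Returns (observations x 9 markers, labels), one observation per
    (donor, draw, treatment).
    """
    X = qpcr.relative_expression_wide(rel_table, list(PANEL_8))
    prot = elisa_ds[(elisa_ds["marker"] == protein) & (elisa_ds["role"] == "sample")]
    prot = prot.copy()
    ids = prot["sample_id"].str.split(".", expand=True)
    prot["donor"], prot["draw"] = ids[0], ids[1].astype(int)
    series = prot.set_index(["donor", "draw", "group"])["absorbance"]
    series.index.names = ["donor", "draw", "treatment"]
    sham_ids = [i for i in series.index if i[2] == "N"]
    series = el.fold_vs_sham(series, sham_ids)
    X = X.join(series.rename(protein), how="inner")
    labels = pd.Series(
        [t for _, _, t in X.index], index=X.index, name="label"
    )
    return X, labels


def run_full_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute every stage; optionally write all stage CSVs to ``out_dir``."""
    cfg = config.reseeded()
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        ct = sim.generate_ct_dataset(cfg.generator)
        elisa_ds = sim.generate_elisa_dataset(cfg.elisa)
        matrix = sim.generate_expression_matrix(cfg.matrix)

        stage("ddct")
        mean_ct = qpcr.collapse_replicates(ct)
        rel = qpcr.delta_ct(mean_ct, cfg.reference_gene)
        fold_rows, fold_results = [], []
        stab = qpcr.reference_stability_filter(
            mean_ct, cfg.reference_gene, "R", "N", cfg.stability_threshold
        )
        for gene in sorted({p.gene for p in cfg.generator.genes}
                           - {"ACTB", "GAPDH"}):
            r = qpcr.fold_change_ddct(rel, gene, "R", "N", stability=stab)
            fold_results.append(r)
            fold_rows.append((gene, r.mean_fold, r.fold_sd, r.t_stat,
                              r.p_value, r.nonoverlap, r.n_pairs))
        fold_changes = pd.DataFrame(
            fold_rows, columns=["gene", "mean_fold", "fold_sd", "t_stat",
                                "p_value", "nonoverlap", "n_pairs"]
        )
        panel = qpcr.select_panel(fold_results, cfg.p_threshold, cfg.fold_threshold)

        stage("panel-score")
        scorer = score.PanelScorer(genes=list(cfg.matrix.genes)).fit(matrix.values)
        raw = scorer.score_samples(matrix.values)
        if cfg.matrix.design == "dose_response":
            rel_scores = []
            for t in cfg.matrix.times:
                ids = matrix.annotations.index[matrix.annotations["time"] == t]
                sham = matrix.annotations.index[
                    (matrix.annotations["time"] == t)
                    & (matrix.annotations["dose"] == 0)
                ]
                rel_scores.append(
                    score.normalize_to_reference_group(raw.loc[ids], sham)
                )
            relative = pd.concat(rel_scores)
            grouping = matrix.annotations[["dose", "time"]]
        else:
            healthy = matrix.annotations.index[
                matrix.annotations["cohort"] == "healthy"
            ]
            relative = score.normalize_to_reference_group(raw, healthy)
            grouping = matrix.annotations["cohort"]
        score_summary, score_pairwise = score.group_summary(relative, grouping)

        stage("elisa")
        elisa_mean = el.average_duplicates(elisa_ds)
        elisa_folds, elisa_tests = _elisa_stage(elisa_mean, cfg)

        stage("classify")
        X, labels = assemble_marker_dataset(rel, elisa_mean)
        groups = [d for d, _, _ in X.index] if cfg.classifier.donor_grouped else None
        ranker = cl.GiniMarkerRanker().fit(X, labels)
        order = cl.MarkerOrder(order=ranker.order_, provenance=ranker.provenance_)
        curve = cl.accuracy_curve(X, labels, order, cfg.classifier, groups)
        cv = cl.cross_validate(X, labels, list(order.order), cfg.classifier, groups)
        screening = cl.diagnostic_screening(cv.confusion)
        screening.accuracy_curve = curve
        screening.marker_order = order
    except Exception as exc:  # pragma: no cover - error path
        log.error("pipeline aborted: %s", exc)
        raise

    provenance = {
        "seed": config.seed,
        "config_hash": _config_hash(cfg),
        "n_observations": int(len(X)),
    }
    report = RunReport(
        fold_changes=fold_changes, panel=panel, score_summary=score_summary,
        score_pairwise=score_pairwise, elisa_folds=elisa_folds,
        elisa_tests=elisa_tests, marker_data=X.assign(label=labels.values),
        marker_order=order, accuracy_curve=curve, screening=screening,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _elisa_stage(elisa_mean: pd.DataFrame, cfg: RunConfig):
    fold_rows, test_rows = [], []
    for marker in elisa_mean["marker"].unique():
        sub = elisa_mean[elisa_mean["marker"] == marker]
        standards = sub[sub["role"] == "standard"]
        # one row per culture aliquot; sample_id names the blood sample and
        # group the treatment arm, so the composite is the unique key
        samples = sub[sub["role"] == "sample"].reset_index(drop=True)
        if len(standards) >= 4:
            curve = el.fit_standard_curve(standards)
            readout = pd.Series(
                el.interpolate(curve, samples["absorbance"]), index=samples.index
            )
        else:  # curve-free marker: sham-relative absorbance
            readout = samples["absorbance"]
        sham = samples.index[samples["group"] == "N"]
        folds = el.fold_vs_sham(readout, sham)
        for i, f in folds.items():
            fold_rows.append((marker, samples.loc[i, "sample_id"],
                              samples.loc[i, "group"], f))
        std = pd.Series(el.standardize(readout), index=readout.index)
        base = std[samples["group"] == "N"]
        for g in CLASS_ORDER[1:]:
            vals = std[samples["group"] == g]
            t, p = el.group_test(vals, base)
            test_rows.append((marker, g, float(folds[samples["group"] == g].mean()),
                              t, p))
    elisa_folds = pd.DataFrame(
        fold_rows, columns=["marker", "sample_id", "group", "fold_vs_sham"]
    )
    elisa_tests = pd.DataFrame(
        test_rows, columns=["marker", "group", "mean_fold", "t_stat", "p_value"]
    )
    return elisa_folds, elisa_tests


def _config_hash(cfg: RunConfig) -> str:
    # repr of the nested dataclass dict is deterministic (insertion-ordered)
    payload = repr(dataclasses.asdict(cfg))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_report(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.fold_changes.to_csv(out_dir / "fold_changes.csv", index=False)
    pd.DataFrame({
        "gene": report.panel.responsive_genes,
        "nonoverlap": [g in report.panel.nonoverlap_genes
                       for g in report.panel.responsive_genes],
    }).to_csv(out_dir / "panel_selection.csv", index=False)
    report.score_summary.to_csv(out_dir / "score_summary.csv", index=False)
    report.score_pairwise.to_csv(out_dir / "score_pairwise.csv", index=False)
    report.elisa_folds.to_csv(out_dir / "elisa_folds.csv", index=False)
    report.elisa_tests.to_csv(out_dir / "elisa_tests.csv", index=False)
    marker_data = report.marker_data.copy()
    marker_data.index = [f"{d}.{w}.{t}" for d, w, t in marker_data.index]
    marker_data.index.name = "observation"
    marker_data.to_csv(out_dir / "marker_dataset.csv")
    pd.DataFrame({
        "rank": range(1, len(report.marker_order.order) + 1),
        "marker": report.marker_order.order,
        "first_pair": [str(report.marker_order.provenance[m][0])
                       for m in report.marker_order.order],
    }).to_csv(out_dir / "marker_order.csv", index=False)
    report.accuracy_curve.to_csv(out_dir / "accuracy_curve.csv", index=False)
    report.screening.confusion.to_csv(out_dir / "confusion_matrix.csv")
    report.screening.metrics.to_csv(out_dir / "screening_metrics.csv")
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2)


def load_run_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Build a RunConfig from a TOML or YAML key-value file.

    Recognised top-level tables: ``generator``, ``elisa_generator`` (a
    subset of simple fields), ``matrix``, ``classifier`` and scalar
    thresholds.  Unknown keys raise.
    """
    path = Path(path)
    if path.suffix == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    cfg = RunConfig()
    simple = {"reference_gene", "stability_threshold", "p_threshold",
              "fold_threshold", "seed"}
    for key, value in data.items():
        if key in simple:
            cfg = dataclasses.replace(cfg, **{key: value})
        elif key == "generator":
            cfg = dataclasses.replace(cfg, generator=sim.default_config(**value))
        elif key == "elisa_generator":
            cfg = dataclasses.replace(cfg, elisa=sim.default_elisa_config(**value))
        elif key == "matrix":
            cfg = dataclasses.replace(cfg, matrix=sim.default_matrix_config(**value))
        elif key == "classifier":
            cfg = dataclasses.replace(cfg, classifier=cl.ClassifierConfig(**value))
        else:
            raise ValueError(f"unknown config key {key!r}")
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg


def configure_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Stderr logging; machine-readable JSON-lines when requested."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        class _Json(logging.Formatter):
            def format(self, record):
                return json.dumps({
                    "level": record.levelname,
                    "name": record.name,
                    "message": record.getMessage(),
                })
        handler.setFormatter(_Json())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)
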