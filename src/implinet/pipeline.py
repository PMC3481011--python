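"""End-to-end pipeline orchestration with file I/O and a run manifest.

A ``PipelineConfig`` (loadable from YAML) names the input files — or asks
for a synthetic cohort pair — and the analysis parameters; ``run_full_
pipeline`` executes screening, per-group network construction, differential
extraction, cross-cohort validation, signature selection, network
evaluation and prognostic modelling, writing every stage product as a
plain-text file plus a deterministic ``manifest.json`` (stage wall-clock
goes to a separate ``timings.json`` so repeated runs are byte-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import __version__
from .clinical import (
    ConfusionTable,
    diagnosis_odds_ratio,
    group_association_test,
    km_logrank,
    knn_train_predict,
    multivariate_cox,
)
from .evaluation import AnnotationCollection
from .model import DifferentialCoexpressionModel
from .synthetic import (
    CohortConfig,
    generate_diagnosis_cohort,
    generate_expression_cohort,
    generate_truth_annotations,
)

__all__ = ["PipelineConfig", "RunManifest", "run_full_pipeline", "synthetic_preset"]

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Everything one run needs; file paths may be None in synthetic mode."""

    out_dir: str
    # file mode
    train_expression: Optional[str] = None
    train_clinical: Optional[str] = None
    test_expression: Optional[str] = None
    test_clinical: Optional[str] = None
    annotation_gmt: tuple[str, ...] = ()
    annotation_interactions: tuple[str, ...] = ()
    expression_format: str = "tsv"
    # synthetic mode
    synthetic: bool = False
    synthetic_seed: int = 0
    synthetic_overrides: dict = field(default_factory=dict)
    # analysis parameters
    hubs: tuple[str, ...] = ()
    alpha: float = 0.05
    quantile_normalize: bool = True
    screen: bool = True
    screen_fdr: bool = False
    n_permutations: int = 200
    stability_iterations: int = 20
    stability_fraction: float = 0.8
    fdr_gene_set: str = "all"
    run_evaluation: bool = True
    run_prognosis: bool = True
    diagnosis: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("annotation_gmt", "annotation_interactions", "hubs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.synthetic:
            for name in ("train_expression", "train_clinical"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required in file mode")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            if not self.hubs:
                raise ValueError("hub gene list is required in file mode")


def synthetic_preset(seed: int = 0, out_dir: str = "implinet_run", **overrides) -> PipelineConfig:
    """A ready-to-run synthetic configuration (default study conditions)."""
    return PipelineConfig(
        out_dir=out_dir,
        synthetic=True,
        synthetic_seed=seed,
        synthetic_overrides=dict(overrides),
        seed=seed,
    )


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict  # stage -> {outputs: {name: sha256}}

    def to_json(self) -> str:
        return json.dumps(
            dict(config=self.config, version=self.version, stages=self.stages),
            indent=2,
            sort_keys=True,
            default=str,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Recorder:
    def __init__(self, out: Path):
        self.out = out
        self.stages: dict = {}
        self.timings: dict = {}

    def stage(self, name: str):
        rec = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.time()
                self_inner.files: list[Path] = []
                rec._current = self_inner
                return self_inner

            def add(self_inner, path: Path):
                self_inner.files.append(Path(path))

            def __exit__(self_inner, exc_type, exc, tb):
                rec.timings[name] = round(time.time() - self_inner.t0, 3)
                if exc_type is not None:
                    logger.error("stage %r failed; partial outputs kept in %s", name, rec.out)
                    return False
                rec.stages[name] = {
                    "outputs": {p.name: _sha256(p) for p in self_inner.files}
                }
                return True

        return _Ctx()


def _load_cohorts(config: PipelineConfig, out: Path, rec: _Recorder):
    """Returns (train_expr, train_clin, test_expr, test_clin, annotations, hubs,
    diagnosis tuple or None)."""
    if config.synthetic:
        with rec.stage("simulate") as st:
            overrides = dict(config.synthetic_overrides)
            cc_train = CohortConfig(seed=config.synthetic_seed, **overrides)
            cc_test = CohortConfig(seed=config.synthetic_seed + 10_000, **overrides)
            train_expr, train_clin, truth = generate_expression_cohort(cc_train)
            test_expr, test_clin, _ = generate_expression_cohort(cc_test)
            test_expr.columns = [f"T{c}" for c in test_expr.columns]
            test_clin = test_clin.copy()
            test_clin.index = test_expr.columns
            test_clin["sample_id"] = test_clin.index
            annotations = generate_truth_annotations(
                truth,
                n_decoy_sets=0,
                seed=config.synthetic_seed,
                genes=list(train_expr.index),
                pair_sharing_rate=0.1,
            )
            hubs = truth.hub_genes
            diag = None
            if config.diagnosis:
                diag_expr, diag_labels = generate_diagnosis_cohort(
                    cc_train, seed=config.synthetic_seed + 20_000, truth=truth
                )
                diag = (diag_expr, diag_labels, truth.signature_genes)
            for name, writer in (
                ("expression_train.tsv", lambda p: pio.write_expression_matrix(train_expr, p)),
                ("clinical_train.tsv", lambda p: pio.write_clinical_table(train_clin, p)),
                ("expression_test.tsv", lambda p: pio.write_expression_matrix(test_expr, p)),
                ("clinical_test.tsv", lambda p: pio.write_clinical_table(test_clin, p)),
                ("annotations.gmt", lambda p: pio.write_gmt(annotations.gene_sets, p)),
                ("interactions.tsv", lambda p: pio.write_interactions(annotations.interactions, p)),
            ):
                path = out / name
                writer(path)
                st.add(path)
        return train_expr, train_clin, test_expr, test_clin, annotations, hubs, diag, truth

    with rec.stage("load") as st:
        train_expr = pio.read_expression_matrix(config.train_expression, config.expression_format)
        train_clin = pio.read_clinical_table(config.train_clinical, train_expr.columns)
        test_expr = test_clin = None
        if config.test_expression:
            test_expr = pio.read_expression_matrix(config.test_expression, config.expression_format)
            test_clin = pio.read_clinical_table(config.test_clinical, test_expr.columns)
            overlap = set(train_expr.columns) & set(test_expr.columns)
            if overlap:
                raise ValueError(
                    f"training and test cohorts overlap: {sorted(overlap)[:5]}"
                )
        annotations = None
        if config.annotation_gmt or config.annotation_interactions:
            annotations = pio.read_annotation_collection(
                config.annotation_gmt, config.annotation_interactions
            )
    return train_expr, train_clin, test_expr, test_clin, annotations, tuple(config.hubs), None, None


def run_full_pipeline(config: PipelineConfig) -> RunManifest:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = _Recorder(out)

    (train_expr, train_clin, test_expr, test_clin,
     annotations, hubs, diag, truth) = _load_cohorts(config, out, rec)

    model = DifferentialCoexpressionModel(
        train_expr, train_clin, hubs,
        test_expr=test_expr, test_clinical=test_clin,
        alpha=config.alpha,
        screen=config.screen,
        quantile_normalize=config.quantile_normalize,
        screen_fdr=config.screen_fdr,
    )

    with rec.stage("screen_and_network") as st:
        results = model.fit()
        from .screening import screen_frame

        if results.survival_screen is not None:
            p = out / "screen_survival.tsv"
            screen_frame(results.survival_screen).to_csv(p, sep="\t", index=False, float_format="%.6g")
            st.add(p)
            p = out / "screen_smoking.tsv"
            screen_frame(results.smoking_screen).to_csv(p, sep="\t", index=False, float_format="%.6g")
            st.add(p)
        p = out / "candidates.txt"
        p.write_text("\n".join(results.candidates.candidates) + "\n")
        st.add(p)
        for grp, net in (("smoker", results.net_smoker), ("nonsmoker", results.net_nonsmoker)):
            sif = out / f"network_{grp}.sif"
            tsv = out / f"network_{grp}.tsv"
            pio.write_network_sif(net, sif, tsv)
            st.add(sif)
            st.add(tsv)

    with rec.stage("differential_and_signature") as st:
        p = out / "differential_edges.tsv"
        results.differential.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
        st.add(p)
        p = out / "validated_edges.tsv"
        results.validated.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
        st.add(p)
        p = out / "signature.tsv"
        results.signature.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
        st.add(p)
        report = dict(
            smoker_genes=list(results.signature.smoker_genes),
            nonsmoker_genes=list(results.signature.nonsmoker_genes),
            hubs=list(hubs),
            adjacency_counts=dict(sorted(results.signature.adjacency_counts.items())),
            counts={k: (None if v is None else int(v)) for k, v in results.counts().items()},
        )
        p = out / "signature.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        st.add(p)
        p = out / "summary.txt"
        p.write_text(results.summary() + "\n")
        st.add(p)

    if config.run_evaluation and annotations is not None and test_expr is not None:
        with rec.stage("evaluate") as st:
            summary = results.evaluate(annotations)
            fdr = results.permutation_fdr(
                annotations, n_perm=config.n_permutations,
                seed=config.seed, gene_set=config.fdr_gene_set,
            )
            stab = results.stability(
                subset_fraction=config.stability_fraction,
                n_iter=config.stability_iterations,
                seed=config.seed,
            )
            p = out / "evaluation.json"
            p.write_text(json.dumps(dict(
                tp=summary.tp, fp=summary.fp, nd=summary.nd,
                network_precision=None if not summary.defined else summary.network_precision,
                q_value=None if not summary.defined else summary.q_value,
                fdr=None if not fdr.defined else fdr.fdr,
                fdr_permutations=fdr.n_perm,
                fdr_empty_permutations=fdr.n_empty,
                stability=None if not stab.defined else stab.stability,
                stability_iterations=config.stability_iterations,
                stability_fraction=config.stability_fraction,
            ), indent=2, sort_keys=True) + "\n")
            st.add(p)

    if config.run_prognosis and results.signature.genes:
        with rec.stage("prognosis") as st:
            risk = results.fit_risk_model()
            p = out / "risk_model.txt"
            p.write_text(risk.to_text())
            st.add(p)
            prog: dict = {}
            for label, expr_c, clin_c in (
                ("train", model.train_expr, train_clin),
                ("test", model.test_expr, test_clin),
            ):
                if expr_c is None:
                    continue
                scores = risk.score(expr_c)
                km = km_logrank(
                    scores, risk.threshold, clin_c["surv_months"], clin_c["event"]
                )
                chi2 = p_assoc = None
                groups_b = (scores >= risk.threshold).astype(int)
                try:
                    chi2, p_assoc = group_association_test(groups_b, clin_c["smoker"])
                except ValueError:
                    pass
                prog[label] = dict(
                    logrank_chi2=km.logrank_chi2, logrank_p=km.logrank_p,
                    group_sizes=km.group_sizes,
                    smoking_association_chi2=chi2, smoking_association_p=p_assoc,
                )
                pd.DataFrame(
                    dict(risk_score=scores, high_risk=groups_b)
                ).to_csv(out / f"prognosis_{label}.tsv", sep="\t", float_format="%.6g")
                st.add(out / f"prognosis_{label}.tsv")
                curves = pd.concat(
                    [c.assign(group=g) for g, c in km.curves.items()], ignore_index=True
                )
                curves.to_csv(out / f"km_curves_{label}.tsv", sep="\t", index=False, float_format="%.6g")
                st.add(out / f"km_curves_{label}.tsv")
            p = out / "prognosis.json"
            p.write_text(json.dumps(prog, indent=2, sort_keys=True) + "\n")
            st.add(p)

    if diag is not None and results.signature.genes:
        with rec.stage("diagnosis") as st:
            diag_expr, diag_labels, _ = diag
            genes = [g for g in results.signature.genes if g in diag_expr.index]
            cols = list(diag_expr.columns)
            n_train = max(2, int(0.6 * len(cols)))
            tr, te = cols[:n_train], cols[n_train:]
            pred, acc = knn_train_predict(
                diag_expr.loc[genes, tr], diag_labels[tr],
                diag_expr.loc[genes, te], diag_labels[te],
            )
            ct = ConfusionTable.from_predictions(pred, diag_labels[te])
            orr = diagnosis_odds_ratio(ct)
            p = out / "diagnosis.json"
            p.write_text(json.dumps(dict(
                accuracy=acc, confusion=dict(a=ct.a, b=ct.b, c=ct.c, d=ct.d),
                odds_ratio=orr.odds_ratio, ci=[orr.ci_low, orr.ci_high],
                p_value=orr.p_value,
            ), indent=2, sort_keys=True) + "\n")
            st.add(p)

    manifest = RunManifest(
        config=dataclasses.asdict(config), version=__version__, stages=rec.stages
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    (out / "timings.json").write_text(
        json.dumps(rec.timings, indent=2, sort_keys=True) + "\n"
    )
    return manifest
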