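"""End-to-end orchestration: DE -> candidate restriction -> PLS scoring ->
bootstrap significance -> network -> ROC, with a reproducible run directory.

Every stage writes its intermediate table; a JSON manifest captures the
configuration, seed, package version and output checksums so a run is fully
reconstructible (same config + seed => identical outputs and manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expression import ExpressionMatrix
from .preprocess import moderated_t_test, select_de
from .targets import CandidatePairSet, restrict_to_de
from .pls import fit_pls, association_scores, score_candidate_pairs
from .significance import evaluate_pairs, call_significant, significant_pairs, REPRESSION
from .network import (
    build_network,
    degree_summary,
    fit_degree_distribution,
    find_modules,
    coregulated_fraction,
    NetworkError,
)
from .roc import matrix_roc
from .simulate import GroundTruth

log = logging.getLogger("mirlink")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    mirna_path: str
    mrna_path: str
    conditions_path: str
    candidates_path: str
    out_dir: str
    de_alpha: float = 0.05
    pls_components: int = 3
    n_boot: int = 1000
    b_threshold: float = 0.8
    p_threshold: float = 0.01
    fdr_threshold: float = 0.05
    target_cutoff: float = 2.5
    alternative: str = REPRESSION
    seed: int = 0
    truth_path: str | None = None

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("de_alpha", 0.0, 1.0),
            ("p_threshold", 0.0, 1.0),
            ("fdr_threshold", 0.0, 1.0),
        ):
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside [{lo}, {hi}]")
        if self.b_threshold < 0:
            raise ValueError("b_threshold must be >= 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in names})


def evaluate_recovery(called: pd.DataFrame, truth: GroundTruth) -> dict:
    """Precision/recall of significant calls against planted edges."""
    sig = significant_pairs(called)
    called_pairs = set(zip(sig["mirna_id"], sig["mrna_id"]))
    planted = truth.edge_pairs()
    tp = len(called_pairs & planted)
    precision = tp / len(called_pairs) if called_pairs else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {
        "n_called": len(called_pairs),
        "n_planted": len(planted),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    stage = "load"
    try:
        mirna = ExpressionMatrix.from_tsv(config.mirna_path, config.conditions_path)
        mrna = ExpressionMatrix.from_tsv(config.mrna_path, config.conditions_path)
        candidates = CandidatePairSet.from_tsv(config.candidates_path)
        log.info(
            "loaded %d miRNAs, %d mRNAs, %d samples, %d candidate pairs",
            mirna.n_features, mrna.n_features, mirna.n_samples, len(candidates),
        )

        stage = "differential_expression"
        de_mirna = moderated_t_test(mirna)
        de_mrna = moderated_t_test(mrna)
        de_mirna.to_csv(out / "de_mirna.tsv", sep="\t", index=False, float_format="%.17g")
        de_mrna.to_csv(out / "de_mrna.tsv", sep="\t", index=False, float_format="%.17g")
        sel_mirna = select_de(de_mirna, config.de_alpha)
        sel_mrna = select_de(de_mrna, config.de_alpha)
        log.info("DE: %d miRNAs, %d mRNAs at alpha=%g",
                 len(sel_mirna.all), len(sel_mrna.all), config.de_alpha)

        stage = "restrict_candidates"
        restricted = restrict_to_de(candidates, sel_mirna.all, sel_mrna.all)
        restricted.to_tsv(out / "candidates_de.tsv")
        log.info("candidates after DE restriction: %d", len(restricted))

        stage = "pls_scoring"
        model = fit_pls(mirna, mrna, v=config.pls_components)
        assoc = association_scores(model, mirna, mrna)
        scored = score_candidate_pairs(assoc, restricted)
        scored.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.17g")

        stage = "significance"
        if len(restricted) > 0:
            table = evaluate_pairs(
                mirna, mrna, restricted,
                n_boot=config.n_boot, seed=config.seed,
                alternative=config.alternative,
            )
            called = call_significant(
                table,
                b_threshold=config.b_threshold,
                p_threshold=config.p_threshold,
                fdr_threshold=config.fdr_threshold,
                alternative=config.alternative,
            )
        else:
            called = pd.DataFrame(
                columns=["mirna_id", "mrna_id", "score", "b", "p_value", "fdr", "significant"]
            )
        called.to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.17g")
        sig = significant_pairs(called) if len(called) else called
        log.info("significant pairs: %d of %d", len(sig), len(called))

        stage = "network"
        summary: dict = {"n_significant_pairs": int(len(sig))}
        if len(sig) > 0:
            net = build_network(sig)
            net.edge_table().to_csv(out / "network_edges.tsv", sep="\t", index=False,
                                    float_format="%.17g")
            net.to_sif(out / "network.sif")
            out_deg, in_deg = degree_summary(net)
            modules = find_modules(net)
            summary.update(
                n_mirna_nodes=len(net.mirnas),
                n_mrna_nodes=len(net.mrnas),
                n_edges=net.n_edges,
                max_out_degree=int(out_deg.max()),
                coregulated_fraction=coregulated_fraction(net),
                n_modules=len(modules),
                modules=[
                    {"mirnas": m.mirna_ids, "shared_targets": m.shared_mrna_ids}
                    for m in modules.modules
                ],
            )
            for model_name, series in (("power_law", out_deg), ("exponential", in_deg)):
                try:
                    fit = fit_degree_distribution(series, model_name)
                    summary[f"{model_name}_fit"] = {
                        "slope_or_exponent": fit.slope_or_exponent,
                        "r_squared": fit.r_squared,
                    }
                except NetworkError as exc:
                    summary[f"{model_name}_fit"] = {"error": str(exc)}
        else:
            summary.update(n_mirna_nodes=0, n_mrna_nodes=0, n_edges=0, n_modules=0)
            log.info("no significant pairs; network stage produced an empty graph")

        stage = "roc"
        net_mirnas = sorted(set(sig["mirna_id"])) if len(sig) else []
        roc_input_ids = net_mirnas or sel_mirna.all
        if roc_input_ids:
            sub = ExpressionMatrix(
                mirna.values.loc[roc_input_ids], mirna.conditions.copy()
            )
            roc_table = matrix_roc(sub)
            roc_table.to_csv(out / "roc.tsv", sep="\t", index=False, float_format="%.17g")
            summary["mean_auc"] = float(roc_table["auc"].mean())

        stage = "recovery"
        if config.truth_path:
            truth = GroundTruth.from_json(config.truth_path)
            recovery = evaluate_recovery(called, truth)
            with open(out / "recovery.json", "w") as fh:
                json.dump(recovery, fh, indent=1)
            summary["recovery"] = recovery

        stage = "manifest"
        outputs = {
            p.name: _sha256(p) for p in sorted(out.iterdir())
            if p.is_file() and p.suffix in (".tsv", ".sif", ".json")
            and p.name != "manifest.json"
        }
        manifest = {
            "package": "mirlink",
            "version": __version__,
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "summary": summary,
            "outputs": outputs,
        }
        manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(manifest, sort_keys=True).encode()
        ).hexdigest()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return out
    except StageError:
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc
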