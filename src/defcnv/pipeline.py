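"""End-to-end workflow: simulate or load a cohort, then run QC, copy-number
estimation, CNV calling, breed summary, covariation blocks, ddPCR
quantification and concordance, and dosage correlation, writing every stage
output plus a run manifest to one directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .covariance import CovariationBlockFinder
from .ddpcr import classify_ddpcr, concordance, quantify_wells
from .depth import (
    ReadCountMatrix,
    ReadDepthCopyNumberEstimator,
    qc_filter_samples,
    summarize_cohort,
)
from .expression import dosage_correlation, read_tpm
from .simulate import default_config, simulate_cohort
from .thresholds import call_cnv

__all__ = ["PipelineError", "run_pipeline", "DEFAULT_PARAMS"]

logger = logging.getLogger("defcnv.pipeline")

DEFAULT_PARAMS = {
    "reference_gene": "TP53",
    "min_coverage": 10.0,
    "threshold_fraction": 0.25,
    "correlation_threshold": 0.9,
    "correlation_method": "pearson",
    "dosage_method": "pearson",
    "dosage_log": False,
    "baseline": "mean",
}


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index_label=None) -> None:
    if index_label is not None:
        df.to_csv(path, sep="\t", index_label=index_label)
    else:
        df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full analysis and return the manifest.

    ``config`` is a dict or a YAML path with keys:

    * ``mode``: ``"simulate"`` or ``"files"``;
    * ``simulate``: for simulate mode, ``{n_samples, seed}`` (seed is
      mandatory — no silent entropy) and optionally any
      :class:`~defcnv.simulate.SyntheticCohortConfig` override handled by
      :func:`~defcnv.simulate.default_config`;
    * ``inputs``: for files mode, paths ``counts`` (TSV with optional
      mean_coverage/breed columns), optional ``expression``, ``wells``,
      ``expected_cn`` (TSV assay_group/expected_cn);
    * ``params``: overrides of :data:`DEFAULT_PARAMS`.

    Outputs are TSV tables in ``outdir``; ``manifest.json`` is written last
    and records the config snapshot, thresholds used, per-stage timings and
    output digests. Any stage failure leaves partial outputs in place and a
    manifest marking the failure.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    mode = config.get("mode", "simulate")
    manifest: dict = {
        "version": __version__,
        "mode": mode,
        "config": config,
        "params": params,
        "stages": {},
        "outputs": {},
        "status": "running",
    }

    # pre-flight: every named input must exist before any stage runs
    if mode == "files":
        inputs = config.get("inputs", {})
        if "counts" not in inputs:
            raise PipelineError("files mode requires inputs.counts")
        for key, path in inputs.items():
            if not Path(path).exists():
                raise PipelineError(f"input file for {key!r} not found: {path}")

    def stage(name):
        logger.info("stage %s", name)
        t0 = time.perf_counter()

        def done():
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 4)
            }

        return done

    try:
        expected_cn = None
        expression = None
        wells = None
        true_cn = None

        if mode == "simulate":
            sim_cfg = dict(config.get("simulate", {}))
            if "seed" not in sim_cfg or sim_cfg["seed"] is None:
                raise PipelineError("simulate mode requires an explicit seed")
            done = stage("simulate")
            cohort_config = default_config(
                seed=int(sim_cfg["seed"]),
                n_samples=int(sim_cfg.get("n_samples", 100)),
            )
            cohort = simulate_cohort(cohort_config)
            matrix = cohort.read_counts
            expression = cohort.expression
            wells = cohort.ddpcr_wells
            true_cn = cohort.true_cn
            expected_cn = {
                g.assay_group: float(g.expected_cn) for g in cohort_config.genes
            }
            matrix.to_tsv(outdir / "counts.tsv")
            _write(true_cn, outdir / "true_cn.tsv", index_label="sample")
            _write(expression, outdir / "expression.tsv", index_label="sample")
            _write(wells, outdir / "ddpcr_wells.tsv")
            done()
        elif mode == "files":
            done = stage("load")
            inputs = config["inputs"]
            matrix = ReadCountMatrix.from_tsv(inputs["counts"])
            if "expression" in inputs:
                expression = read_tpm(inputs["expression"])
            if "wells" in inputs:
                wells = pd.read_csv(inputs["wells"], sep="\t")
            if "expected_cn" in inputs:
                tab = pd.read_csv(inputs["expected_cn"], sep="\t")
                expected_cn = dict(
                    zip(tab["assay_group"], tab["expected_cn"].astype(float))
                )
            done()
        else:
            raise PipelineError(f"unknown mode {mode!r}")

        done = stage("qc")
        if matrix.mean_coverage is not None:
            matrix, qc = qc_filter_samples(matrix, params["min_coverage"])
            logger.info(
                "QC: excluded %d samples below %.1fx", qc.n_excluded, qc.threshold
            )
            manifest["qc_excluded"] = {
                str(k): float(v) for k, v in qc.excluded.items()
            }
        done()

        done = stage("cn_estimate")
        est = ReadDepthCopyNumberEstimator(
            reference_gene=params["reference_gene"],
            expected_cn=expected_cn,
            baseline=params["baseline"],
        )
        cn = est.fit_transform(matrix)
        _write(cn.round(4), outdir / "cn_matrix.tsv", index_label="sample")
        _write(
            est.expected_cn_.rename("expected_cn").to_frame(),
            outdir / "expected_cn.tsv",
            index_label="assay_group",
        )
        done()

        done = stage("cn_call")
        logger.info("threshold fraction: %s", params["threshold_fraction"])
        calls = call_cnv(cn, est.expected_cn_, fraction=params["threshold_fraction"])
        _write(calls, outdir / "calls.tsv")
        done()

        done = stage("summarize")
        if matrix.breed is not None:
            breed_summary, gene_ranges = summarize_cohort(calls, matrix.breed)
            _write(breed_summary, outdir / "breed_summary.tsv")
            _write(gene_ranges, outdir / "gene_ranges.tsv")
        done()

        done = stage("covariance")
        logger.info(
            "correlation threshold: %s (%s)",
            params["correlation_threshold"],
            params["correlation_method"],
        )
        finder = CovariationBlockFinder(
            threshold=params["correlation_threshold"],
            method=params["correlation_method"],
        ).fit(cn)
        _write(finder.pairs_, outdir / "covary_pairs.tsv")
        blocks_df = pd.DataFrame(
            [
                {
                    "members": ",".join(b.members),
                    "n_members": len(b),
                    "min_pairwise_r": b.min_pairwise_r,
                    "threshold": b.threshold,
                }
                for b in finder.blocks_
            ],
            columns=["members", "n_members", "min_pairwise_r", "threshold"],
        )
        _write(blocks_df, outdir / "covary_blocks.tsv")
        done()

        if wells is not None:
            done = stage("ddpcr")
            results = quantify_wells(wells)
            _write(results.round(6), outdir / "ddpcr_results.tsv")
            ddpcr_calls = classify_ddpcr(
                results, expected_cn, fraction=params["threshold_fraction"]
            )
            _write(ddpcr_calls, outdir / "ddpcr_calls.tsv")
            report = concordance(
                cn, results, expected_cn, fraction=params["threshold_fraction"]
            )
            _write(
                pd.DataFrame([report.__dict__]), outdir / "ddpcr_concordance.tsv"
            )
            done()

        if expression is not None:
            done = stage("dosage")
            dosage = dosage_correlation(
                cn,
                expression,
                method=params["dosage_method"],
                log_transform=params["dosage_log"],
            )
            _write(dosage.round(6), outdir / "dosage.tsv")
            done()

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finalize_manifest(manifest, outdir)
        raise

    _finalize_manifest(manifest, outdir)
    return manifest


def _finalize_manifest(manifest: dict, outdir: Path) -> None:
    for path in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
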