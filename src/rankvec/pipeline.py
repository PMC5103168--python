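"""End-to-end orchestration: simulate -> normalize -> rankprod -> vectors -> categories.

Every stage is file-based (reads its declared inputs from the run directory,
writes its declared outputs there), so chaining the stages individually and
calling :func:`run_all` produce byte-identical files.  One master seed
deterministically derives an independent substream per stage, tissue and
analysis, letting a single stage be re-run reproducibly.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .categories import categorize_tissue, truth_confusion
from .io_model import (
    CountMatrix,
    DesignError,
    RunConfig,
    SampleSheet,
    read_count_matrix,
    read_sample_sheet,
    validate_design,
)
from .normalization import expression_matrix, pca_qc
from .rankprod import CONTRAST_ORDER, six_contrasts
from .synthetic_data import SimulationParams, read_truth, simulate_counts, write_truth
from .vector_analysis import ANALYSES, run_vector_analysis

log = logging.getLogger("rankvec")

_FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def derive_seed(master_seed: int, *tokens: str) -> int:
    """Deterministic per-stage substream seed (< 2**31) from the master seed."""
    keys = [int(master_seed) & 0xFFFFFFFF] + [zlib.crc32(t.encode()) for t in tokens]
    return int(np.random.SeedSequence(keys).generate_state(1)[0] % (2**31))


# canonical file names inside a run directory -------------------------------

def counts_path(outdir: Path) -> Path:
    return Path(outdir) / "counts.tsv"


def samples_path(outdir: Path) -> Path:
    return Path(outdir) / "samples.tsv"


def truth_path(outdir: Path) -> Path:
    return Path(outdir) / "truth.tsv"


def expr_path(outdir: Path, tissue: str) -> Path:
    return Path(outdir) / f"{tissue}.expr.tsv"


def pca_path(outdir: Path, tissue: str) -> Path:
    return Path(outdir) / f"{tissue}.pca.tsv"


def contrast_path(outdir: Path, tissue: str, contrast: str) -> Path:
    return Path(outdir) / f"{tissue}.{contrast}.rankprod.tsv"


def table1_path(outdir: Path, tissue: str) -> Path:
    return Path(outdir) / f"{tissue}.summary_table1.tsv"


def vectors_path(outdir: Path, tissue: str, analysis: str) -> Path:
    return Path(outdir) / f"{tissue}.{analysis}.vectors.tsv"


def assignments_path(outdir: Path, tissue: str) -> Path:
    return Path(outdir) / f"{tissue}.assignments.tsv"


def table2_path(outdir: Path, tissue: str) -> Path:
    return Path(outdir) / f"{tissue}.summary_table2.tsv"


def confusion_path(outdir: Path, tissue: str) -> Path:
    return Path(outdir) / f"{tissue}.confusion.tsv"


def _require(path: Path, stage: str) -> Path:
    if not Path(path).is_file():
        raise PipelineError(f"stage {stage!r}: required input {path} does not exist")
    return Path(path)


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir: Path, params: SimulationParams) -> list[Path]:
    """Write counts.tsv, samples.tsv and truth.tsv for a synthetic run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, ss, truth = simulate_counts(params)
    cm.to_tsv(counts_path(outdir))
    ss.to_tsv(samples_path(outdir))
    write_truth(truth, truth_path(outdir))
    log.info("simulate: %d genes x %d samples, %d planted genes",
             cm.shape[0], cm.shape[1], len(truth))
    return [counts_path(outdir), samples_path(outdir), truth_path(outdir)]


def _load_inputs(
    outdir: Path, counts: Path | None, samples: Path | None, stage: str
) -> tuple[CountMatrix, SampleSheet]:
    cpath = _require(counts or counts_path(outdir), stage)
    spath = _require(samples or samples_path(outdir), stage)
    cm = read_count_matrix(cpath)
    ss = read_sample_sheet(spath)
    ss.validate_pairing(cm)
    return cm, ss


def _tissues_present(ss: SampleSheet) -> list[str]:
    seen = list(dict.fromkeys(ss.table["tissue"]))
    return seen


def stage_normalize(
    outdir: Path,
    config: RunConfig,
    counts: Path | None = None,
    samples: Path | None = None,
    tissues: Sequence[str] | None = None,
) -> list[Path]:
    """Per tissue: write the log2 expression matrix and PCA QC coordinates."""
    outdir = Path(outdir)
    cm, ss = _load_inputs(outdir, counts, samples, "normalize")
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for tissue in tissues or _tissues_present(ss):
        sub = ss.for_tissue(tissue)
        em = expression_matrix(cm.subset_samples(sub.sample_ids), config)
        written.append(_write(em, expr_path(outdir, tissue), index=True))
        n_components = min(3, em.shape[1] - 1)
        coords, ratios = pca_qc(em, n_components=n_components)
        coords = coords.copy()
        for i, r in enumerate(ratios):
            coords[f"var_frac_PC{i + 1}"] = r
        written.append(_write(coords, pca_path(outdir, tissue), index=True))
        log.info("normalize[%s]: %d genes, %d samples", tissue, *em.shape)
    return written


def _read_expr(outdir: Path, tissue: str, stage: str) -> pd.DataFrame:
    path = _require(expr_path(outdir, tissue), stage)
    return pd.read_csv(path, sep="\t", index_col=0)


def stage_rankprod(
    outdir: Path,
    config: RunConfig,
    tissue: str,
    samples: Path | None = None,
) -> list[Path]:
    """Six contrasts of one tissue: per-contrast tables plus the count summary."""
    outdir = Path(outdir)
    em = _read_expr(outdir, tissue, "rankprod")
    ss = read_sample_sheet(_require(samples or samples_path(outdir), "rankprod"))
    rng = np.random.default_rng(derive_seed(config.seed, "rankprod", tissue))
    six = six_contrasts(em, ss, tissue, config, rng)
    written = []
    for name, res in six.results.items():
        table = pd.concat([res.up, res.down], ignore_index=True)
        written.append(_write(table, contrast_path(outdir, tissue, name)))
    written.append(_write(six.summary, table1_path(outdir, tissue)))
    log.info("rankprod[%s]: significant up/down per contrast: %s", tissue,
             six.summary.to_dict("records"))
    return written


def _universe_from_files(outdir: Path, config: RunConfig, tissue: str) -> list[str]:
    universe: set[str] = set()
    for g1, g2 in CONTRAST_ORDER:
        path = _require(contrast_path(outdir, tissue, f"{g1}_vs_{g2}"), "vectors")
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        universe.update(df.loc[df["pfp"] <= config.fdr_threshold, "gene_id"])
    return sorted(universe)


def stage_vectors(
    outdir: Path,
    config: RunConfig,
    tissue: str,
    samples: Path | None = None,
    normalize_vectors: bool = False,
) -> list[Path]:
    """Both vector analyses over the pfp-filtered gene universe of one tissue."""
    outdir = Path(outdir)
    em = _read_expr(outdir, tissue, "vectors")
    ss = read_sample_sheet(_require(samples or samples_path(outdir), "vectors"))
    universe = _universe_from_files(outdir, config, tissue)
    log.info("vectors[%s]: universe of %d genes", tissue, len(universe))
    written = []
    for name in ANALYSES:
        rng = np.random.default_rng(derive_seed(config.seed, "vectors", tissue, name))
        table = run_vector_analysis(
            em, ss, tissue, name, universe, config, rng,
            normalize_vectors=normalize_vectors,
        )
        only1 = table["cls"].isin(("only1_up", "only1_down")).sum() if len(table) else 0
        if only1:
            log.warning(
                "vectors[%s/%s]: %d genes respond only in the B-exposed "
                "environment (only1_*); these map to no behavioural category",
                tissue, name, only1,
            )
        written.append(_write(table, vectors_path(outdir, tissue, name)))
    return written


def stage_categories(
    outdir: Path,
    config: RunConfig,
    tissue: str,
    truth: Path | None = None,
) -> list[Path]:
    """Combine the two vector analyses into behavioural category assignments."""
    del config  # thresholds were applied upstream; kept for a uniform signature
    outdir = Path(outdir)
    post = pd.read_csv(
        _require(vectors_path(outdir, tissue, "postnatal_response"), "categories"),
        sep="\t", dtype={"gene_id": str},
    )
    pre = pd.read_csv(
        _require(vectors_path(outdir, tissue, "prenatal_response"), "categories"),
        sep="\t", dtype={"gene_id": str},
    )
    assignments, summary = categorize_tissue(post, pre, tissue)
    written = [
        _write(assignments, assignments_path(outdir, tissue)),
        _write(summary, table2_path(outdir, tissue)),
    ]
    log.info("categories[%s]: %s", tissue,
             dict(zip(summary["category"], summary["n_genes"])))
    if truth is not None:
        truth_df = read_truth(_require(truth, "categories"))
        gene_ids = pd.read_csv(
            _require(expr_path(outdir, tissue), "categories"),
            sep="\t", usecols=[0], dtype=str,
        ).iloc[:, 0].tolist()
        confusion = truth_confusion(assignments, truth_df, gene_ids)
        written.append(_write(confusion.reset_index(), confusion_path(outdir, tissue)))
    return written


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    version: str
    config: dict
    seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def run_all(
    config: RunConfig,
    outdir: Path,
    sim_params: SimulationParams | None = None,
    counts: Path | None = None,
    samples: Path | None = None,
    truth: Path | None = None,
    tissues: Sequence[str] | None = None,
) -> RunManifest:
    """Execute every stage and write a manifest.

    Input is either a :class:`SimulationParams` (synthetic run; the generator
    seed is derived from the config master seed) or existing counts/samples
    paths.  Any stage failure raises :class:`PipelineError` naming the stage;
    the manifest then records which stages completed.
    """
    outdir = Path(outdir)
    if sim_params is None and counts is None:
        raise PipelineError("stage 'input': provide sim_params or counts/samples paths")
    if sim_params is not None and counts is not None:
        raise PipelineError("stage 'input': simulate and explicit counts are exclusive")
    if sim_params is None:
        counts = _require(counts, "input")
        samples = _require(samples or Path(counts).parent / "samples.tsv", "input")
    manifest = RunManifest(version=__version__, config=config.to_dict())
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def run_stage(name: str, fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except PipelineError:
            manifest.failed_stage = name
            raise
        except Exception as exc:
            manifest.failed_stage = name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest.timings_s[name] = round(time.perf_counter() - start, 3)
        manifest.completed_stages.append(name)
        written.extend(out)
        return out

    if sim_params is not None:
        sim_params = SimulationParams(
            **{**sim_params.__dict__, "seed": derive_seed(config.seed, "simulate")}
        )
        manifest.seeds["simulate"] = sim_params.seed
        run_stage("simulate", stage_simulate, outdir, sim_params)
        counts, samples = counts_path(outdir), samples_path(outdir)
        truth = truth_path(outdir)

    run_stage("normalize", stage_normalize, outdir, config, counts, samples, tissues)
    ss = read_sample_sheet(samples)
    for tissue in tissues or _tissues_present(ss):
        manifest.seeds[f"rankprod/{tissue}"] = derive_seed(config.seed, "rankprod", tissue)
        for name in ANALYSES:
            manifest.seeds[f"vectors/{tissue}/{name}"] = derive_seed(
                config.seed, "vectors", tissue, name
            )
        run_stage(f"rankprod/{tissue}", stage_rankprod, outdir, config, tissue, samples)
        run_stage(f"vectors/{tissue}", stage_vectors, outdir, config, tissue, samples)
        run_stage(
            f"categories/{tissue}", stage_categories, outdir, config, tissue, truth
        )

    for path in written:
        manifest.checksums[Path(path).name] = _sha256(path)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
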