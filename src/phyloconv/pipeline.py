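"""End-to-end orchestration: trim -> fit H0/H1/H1' -> dSSLS verdict ->
ancestral reconstruction -> CCS Poisson test -> PSG intersection.

Configuration is one YAML file, schema-checked with unknown keys rejected
(with a suggestion when a near-miss is found).  Every run writes a manifest
recording the seed, the fully defaulted configuration and its hash, so runs
are self-describing; report TSVs are byte-deterministic given config + seed
(wall-clock timings go to the log only).  A gene that fails any stage is
quarantined (logged and counted), never fatal.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ccs import ccs_gene_test, adaptive_convergence_intersect
from .dssls import classify_gene, compute_delta
from .errors import ConfigError
from .likelihood import fit_gene, marginal_ancestral_states
from .models import build_model
from .seqio import Alignment, read_fasta, translate_codons, trim_alignment
from .trees import (
    PhyloTree,
    force_clade,
    matched_distortion_control,
    parse_newick,
    verify_h1prime,
)

log = logging.getLogger(__name__)

_SCHEMA = {
    "paths": {
        "genes_dir": str,
        "species_tree": str,
        "targets": (str, list),
        "control_taxa": (str, list, type(None)),
        "h1": (str, type(None)),
        "h1prime": (str, type(None)),
        "psg_list": (str, type(None)),
        "out_dir": str,
    },
    "thresholds": {
        "alpha": float,
        "posterior_min": float,
        "max_gap_fraction": float,
    },
    "model": {
        "dssls": str,
        "ccs": str,
        "gamma_categories": int,
        "empirical_frequencies": bool,
    },
    "alphabet": str,
    "seed": int,
    "threads": int,
    "stages": {"dssls": bool, "ccs": bool},
}

_DEFAULTS = {
    "thresholds": {"alpha": 0.05, "posterior_min": 0.7, "max_gap_fraction": 0.5},
    "model": {
        "dssls": "WAG",
        "ccs": "JTT",
        "gamma_categories": 4,
        "empirical_frequencies": True,
    },
    "alphabet": "aa",
    "seed": 0,
    "threads": 1,
    "stages": {"dssls": True, "ccs": True},
}


@dataclass
class PipelineConfig:
    genes_dir: Path
    species_tree: Path
    targets: list[str]
    out_dir: Path
    control_taxa: list[str] | None = None
    h1: Path | None = None
    h1prime: Path | None = None
    psg_list: Path | None = None
    alpha: float = 0.05
    posterior_min: float = 0.7
    max_gap_fraction: float = 0.5
    dssls_model: str = "WAG"
    ccs_model: str = "JTT"
    gamma_categories: int = 4
    empirical_frequencies: bool = True
    alphabet: str = "aa"
    seed: int = 0
    threads: int = 1
    run_dssls: bool = True
    run_ccs: bool = True
    raw: dict = field(default_factory=dict)


def _check_keys(given: dict, schema: dict, prefix: str = "") -> None:
    for key in given:
        if key not in schema:
            hint = difflib.get_close_matches(key, schema.keys(), n=1)
            msg = f"unknown configuration key {prefix}{key!r}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            raise ConfigError(msg)
        if isinstance(schema[key], dict):
            if not isinstance(given[key], dict):
                raise ConfigError(f"{prefix}{key} must be a mapping")
            _check_keys(given[key], schema[key], prefix=f"{prefix}{key}.")


def _read_list(value, base: Path) -> list[str]:
    if isinstance(value, list):
        return [str(x) for x in value]
    path = base / value if not Path(value).is_absolute() else Path(value)
    return [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default, and schema-check a YAML pipeline configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    _check_keys(raw, _SCHEMA)
    base = path.parent
    paths = raw.get("paths", {})
    for req in ("genes_dir", "species_tree", "targets", "out_dir"):
        if req not in paths:
            raise ConfigError(f"missing required path: paths.{req}")

    def resolve(p):
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    thr = {**_DEFAULTS["thresholds"], **raw.get("thresholds", {})}
    if not 0.0 < thr["alpha"] < 1.0:
        raise ConfigError("thresholds.alpha must lie in (0, 1)")
    if not 0.0 <= thr["posterior_min"] <= 1.0:
        raise ConfigError("thresholds.posterior_min must lie in [0, 1]")
    if not 0.0 <= thr["max_gap_fraction"] <= 1.0:
        raise ConfigError("thresholds.max_gap_fraction must lie in [0, 1]")
    mdl = {**_DEFAULTS["model"], **raw.get("model", {})}
    stages = {**_DEFAULTS["stages"], **raw.get("stages", {})}
    alphabet = raw.get("alphabet", _DEFAULTS["alphabet"])
    if alphabet not in ("aa", "codon"):
        raise ConfigError("alphabet must be 'aa' or 'codon'")

    genes_dir = resolve(paths["genes_dir"])
    if not genes_dir.is_dir():
        raise ConfigError(f"genes_dir does not exist: {genes_dir}")
    species_tree = resolve(paths["species_tree"])
    if not species_tree.is_file():
        raise ConfigError(f"species_tree does not exist: {species_tree}")

    cfg = PipelineConfig(
        genes_dir=genes_dir,
        species_tree=species_tree,
        targets=_read_list(paths["targets"], base),
        out_dir=resolve(paths["out_dir"]),
        control_taxa=(
            _read_list(paths["control_taxa"], base)
            if paths.get("control_taxa")
            else None
        ),
        h1=resolve(paths.get("h1")),
        h1prime=resolve(paths.get("h1prime")),
        psg_list=resolve(paths.get("psg_list")),
        alpha=float(thr["alpha"]),
        posterior_min=float(thr["posterior_min"]),
        max_gap_fraction=float(thr["max_gap_fraction"]),
        dssls_model=mdl["dssls"],
        ccs_model=mdl["ccs"],
        gamma_categories=int(mdl["gamma_categories"]),
        empirical_frequencies=bool(mdl["empirical_frequencies"]),
        alphabet=alphabet,
        seed=int(raw.get("seed", 0)),
        threads=int(raw.get("threads", 1)),
        run_dssls=bool(stages["dssls"]),
        run_ccs=bool(stages["ccs"]),
        raw=raw,
    )
    return cfg


def _gene_files(genes_dir: Path) -> list[Path]:
    files: list[Path] = []
    for pat in ("*.fa", "*.fasta", "*.fsa"):
        files.extend(genes_dir.glob(pat))
    return sorted(set(files))


def _process_gene(
    path: Path,
    cfg: PipelineConfig,
    h0: PhyloTree,
    h1: PhyloTree,
    h1p: PhyloTree,
):
    aln = read_fasta(path, cfg.alphabet)
    aln, _ = trim_alignment(aln, cfg.max_gap_fraction, drop_ambiguous=True)
    if cfg.alphabet == "codon":
        aln = translate_codons(aln, internal_stop="X")
    if aln.n_columns == 0:
        raise ValueError("no columns left after trimming")
    freqs = "empirical" if cfg.empirical_frequencies else "model"
    out: dict = {"gene_id": aln.gene_id, "n_sites": aln.n_columns}
    if cfg.run_dssls:
        spec = dict(
            frequencies=freqs, alignment=aln, gamma_shape=1.0,
            n_categories=cfg.gamma_categories,
        )
        fit0 = fit_gene(aln, h0, build_model(cfg.dssls_model, **spec))
        fit1 = fit_gene(aln, h1, build_model(cfg.dssls_model, **spec))
        fit1p = fit_gene(aln, h1p, build_model(cfg.dssls_model, **spec))
        res = classify_gene(compute_delta(fit0, fit1, fit1p), alpha=cfg.alpha)
        out["dssls"] = res
    if cfg.run_ccs:
        ccs_model = build_model(
            cfg.ccs_model, frequencies=freqs, alignment=aln,
            gamma_shape=1.0, n_categories=cfg.gamma_categories,
        )
        fit_ccs = fit_gene(aln, h0, ccs_model)
        recon = marginal_ancestral_states(fit_ccs)
        out["ccs"] = ccs_gene_test(
            fit_ccs, recon, aln, cfg.targets,
            posterior_min=cfg.posterior_min, alpha=cfg.alpha,
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages over every gene; returns a summary dict and
    writes report TSVs, a manifest, and a run log under ``out_dir``."""
    cfg = config
    out_dir = cfg.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    run_log = open(out_dir / "run.log", "w")

    def stage_log(gene, stage, status, t0):
        run_log.write(
            f"{gene}\t{stage}\t{status}\t{time.perf_counter() - t0:.3f}s\n"
        )

    files = _gene_files(cfg.genes_dir)
    if not files:
        raise ConfigError(f"no gene alignments found in {cfg.genes_dir}")

    h0 = parse_newick(cfg.species_tree.read_text(), role_tag="H0")
    if cfg.h1 is not None:
        h1 = parse_newick(cfg.h1.read_text(), role_tag="H1")
    else:
        h1 = force_clade(h0, cfg.targets)
    if cfg.h1prime is not None:
        h1p = parse_newick(cfg.h1prime.read_text(), role_tag="H1prime")
        verify_h1prime(h0, h1, h1p, cfg.targets)
    else:
        if not cfg.control_taxa:
            raise ConfigError(
                "either paths.h1prime or paths.control_taxa is required"
            )
        h1p = matched_distortion_control(h0, h1, cfg.targets, cfg.control_taxa)

    results = []
    quarantined = []

    def worker(path: Path):
        return _process_gene(path, cfg, h0, h1, h1p)

    if cfg.threads > 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=cfg.threads)(
            delayed(_safe)(worker, f) for f in files
        )
    else:
        outcomes = [_safe(worker, f) for f in files]
    for f, (res, err) in zip(files, outcomes):
        t0 = time.perf_counter()
        if err is not None:
            quarantined.append((f.stem, err))
            stage_log(f.stem, "gene", f"QUARANTINED: {err}", t0)
        else:
            results.append(res)
            stage_log(res["gene_id"], "gene", "ok", t0)

    if len(quarantined) > len(files) / 2:
        run_log.close()
        raise ConfigError(
            f"{len(quarantined)} of {len(files)} genes failed; check that the "
            "tree and alignments share taxa"
        )

    psg_ids: set[str] = set()
    if cfg.psg_list is not None:
        psg_ids = set(_read_list(cfg.psg_list, cfg.psg_list.parent))

    summary = _write_reports(cfg, results, quarantined, psg_ids, out_dir)
    run_log.close()
    return summary


def _safe(fn, arg):
    try:
        return fn(arg), None
    except Exception as exc:  # quarantine, never fatal per gene
        return None, str(exc)


def _write_reports(cfg, results, quarantined, psg_ids, out_dir: Path) -> dict:
    summary: dict = {
        "n_genes_in": len(results) + len(quarantined),
        "n_genes_ok": len(results),
        "n_quarantined": len(quarantined),
    }
    if cfg.run_dssls:
        with open(out_dir / "dssls_results.tsv", "w") as fh:
            fh.write(
                "# dSSLS per-gene results; site indices 1-based\n"
                "gene_id\tn_sites\tmean_dL_H0_H1\tmean_dL_H0_H1prime\t"
                "ks_D\tks_p\tverdict\n"
            )
            for r in results:
                d = r["dssls"]
                fh.write(
                    f"{r['gene_id']}\t{r['n_sites']}\t"
                    f"{d.mean_delta_H0_H1:.6f}\t{d.mean_delta_H0_H1prime:.6f}\t"
                    f"{d.ks_statistic:.6f}\t{d.ks_p:.6g}\t{d.verdict}\n"
                )
        n_fav = sum(
            r["dssls"].verdict == "favors_H1" for r in results
        )
        summary["dssls_favors_H1_fraction"] = (
            n_fav / len(results) if results else float("nan")
        )
    if cfg.run_ccs:
        nonrandom = set()
        with open(out_dir / "ccs_genes.tsv", "w") as fh:
            fh.write(
                "# CCS per-gene Poisson test (parallel+convergent pooled)\n"
                "gene_id\tobserved\tn_parallel\tn_convergent\texpected\t"
                "poisson_p\tnonrandom\tpsg\tadaptive\n"
            )
            for r in results:
                c = r["ccs"]
                is_psg = c.gene_id in psg_ids
                adaptive = c.nonrandom and is_psg
                if c.nonrandom:
                    nonrandom.add(c.gene_id)
                fh.write(
                    f"{c.gene_id}\t{c.observed_count}\t{c.n_parallel}\t"
                    f"{c.n_convergent}\t{c.expected_count:.6f}\t"
                    f"{c.poisson_p:.6g}\t{int(c.nonrandom)}\t{int(is_psg)}\t"
                    f"{int(adaptive)}\n"
                )
        with open(out_dir / "ccs_calls.tsv", "w") as fh:
            fh.write(
                "# convergent/parallel site calls; site indices 1-based\n"
                "gene_id\tsite\ttaxonA\ttaxonB\ttype\tderived\t"
                "parentA\tparentB\tmrca\tmin_posterior\n"
            )
            for r in results:
                for call in r["ccs"].calls:
                    fh.write(
                        f"{call.gene_id}\t{call.site}\t"
                        f"{call.lineage_pair[0]}\t{call.lineage_pair[1]}\t"
                        f"{call.call_type}\t{call.derived_state}\t"
                        f"{call.parent_states[0]}\t{call.parent_states[1]}\t"
                        f"{call.mrca_state}\t{call.min_posterior:.4f}\n"
                    )
        adaptive_set = adaptive_convergence_intersect(nonrandom, psg_ids)
        with open(out_dir / "adaptive_convergence.txt", "w") as fh:
            for g in sorted(adaptive_set):
                fh.write(g + "\n")
        summary["ccs_nonrandom_fraction"] = (
            len(nonrandom) / len(results) if results else float("nan")
        )
        summary["adaptive_convergence_genes"] = sorted(adaptive_set)

    cfg_text = yaml.safe_dump(cfg.raw, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "defaults_applied": {
            "alpha": cfg.alpha,
            "posterior_min": cfg.posterior_min,
            "max_gap_fraction": cfg.max_gap_fraction,
            "dssls_model": cfg.dssls_model,
            "ccs_model": cfg.ccs_model,
            "gamma_categories": cfg.gamma_categories,
            "empirical_frequencies": cfg.empirical_frequencies,
        },
        "n_genes_in": summary["n_genes_in"],
        "n_quarantined": summary["n_quarantined"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
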