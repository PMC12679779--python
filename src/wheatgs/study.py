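"""One-command end-to-end study: simulate/read -> QC -> H2 -> models -> CV.

``run_study`` executes the full pipeline declared by a
:class:`wheatgs.config.RunConfig` and writes its outputs (variance
components, correlations, long- and wide-format evaluation tables, QC
report, manifest) under the configured output directory.  All randomness
fans out from the master seed through a counter-based seed stream, so the
emitted CSVs are a pure function of the configuration.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from wheatgs import io
from wheatgs.config import RunConfig
from wheatgs.evalharness import (EvalScheme, run_cross_condition, run_kfcv,
                                 run_loocv, summarize)
from wheatgs.genoqc import QCConfig, run_qc
from wheatgs.gsmodels.registry import make_model
from wheatgs.phenotypes import CWR
from wheatgs.quantgen import fit_mixed_model, heritability, trait_correlations, variance_table
from wheatgs.simdata import SimConfig, simulate_study

__all__ = ["run_study", "seed_for"]

log = logging.getLogger(__name__)

CROSS_CONFIGS = (("WW", "WS"), ("WS", "WW"), (CWR, "WS"), (CWR, "WW"))


def seed_for(master: int, *labels) -> int:
    """Deterministic per-(trait, model, scheme) seed below 2**31."""
    import hashlib

    digest = hashlib.sha256("\x1f".join(str(l) for l in labels).encode()).digest()
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF,
                                 int.from_bytes(digest[:4], "big")])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _load_data(cfg: RunConfig):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        traits = sim.pop("traits", None)
        simcfg = SimConfig(seed=sim.pop("seed", cfg.seed), **sim)
        geno, pheno, truths = simulate_study(simcfg, traits)
        return geno, pheno, {"mode": "simulate", "sim_config": simcfg}
    geno = io.read_genotypes(cfg.inputs["genotypes"])
    pheno = io.read_phenotypes(cfg.inputs["phenotypes"])
    pheno = pheno.check_against_genotypes(geno.line_ids)
    if pheno.unmatched:
        log.warning("dropped %d phenotype-only genotypes: %s",
                    len(pheno.unmatched), pheno.unmatched[:5])
    return geno, pheno, {"mode": "read", "unmatched": pheno.unmatched}


def _evaluate(cfg: RunConfig, geno, pheno, h2_table, outputs):
    X = geno.dosages
    marker_ids = geno.marker_ids
    lines = list(geno.line_ids)
    results = []
    regimes = pheno.regimes
    for sch in cfg.schemes:
        sch = dict(sch)
        kind = sch.pop("kind")
        pairs = sch.pop("configurations", None) or CROSS_CONFIGS
        scheme_regimes = sch.pop("regimes", None)
        sch.pop("seed", None)
        for trait in pheno.traits:
            if kind == "cross_condition":
                for train_r, test_r in pairs:
                    y_tr = pheno.line_means(trait, train_r).reindex(lines)
                    y_te = pheno.line_means(trait, test_r).reindex(lines)
                    if y_tr.isna().any() or y_te.isna().any():
                        raise ValueError(f"lines missing phenotypes for {trait}")
                    h2 = h2_table.get((trait, test_r), np.nan)
                    for name in cfg.models:
                        seed = seed_for(cfg.seed, trait, name, kind, train_r, test_r)
                        factory = _factory(cfg, name, seed)
                        results.append(run_cross_condition(
                            X, y_tr.to_numpy(), y_te.to_numpy(), factory,
                            h2_test=h2, trait=trait,
                            configuration=f"{train_r}->{test_r}",
                            model_name=name))
                continue
            eval_regimes = scheme_regimes or (
                list(regimes) + ([CWR] if len(regimes) > 1 else []))
            sch_kwargs = dict(sch)
            for regime in eval_regimes:
                y = pheno.line_means(trait, regime).reindex(lines)
                if y.isna().any():
                    raise ValueError(f"lines missing phenotypes for {trait}/{regime}")
                h2 = h2_table.get((trait, regime), np.nan)
                for name in cfg.models:
                    seed = seed_for(cfg.seed, trait, name, kind, regime)
                    factory = _factory(cfg, name, seed)
                    if kind == "kfcv":
                        scheme = EvalScheme(kind="kfcv", seed=seed, **sch_kwargs)
                        results.append(run_kfcv(X, y.to_numpy(), factory, scheme,
                                                h2=h2, trait=trait, regime=regime,
                                                model_name=name))
                    else:
                        results.append(run_loocv(X, y.to_numpy(), factory, h2=h2,
                                                 trait=trait, regime=regime,
                                                 model_name=name))
    return results


def _factory(cfg: RunConfig, name: str, seed: int):
    params = dict(cfg.model_params.get(name, {}))
    return lambda: make_model(name, seed=seed, **params)


def run_study(config: RunConfig | dict, output_dir=None) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written).

    Any stage failure is recorded in the manifest with partial outputs
    preserved; the manifest's ``status`` is then ``"failed"``.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    outdir = Path(output_dir or cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))

    from wheatgs import __version__

    manifest = {
        "config": cfg.as_dict(),
        "config_hash": cfg.content_hash(),
        "package_version": __version__,
        "master_seed": cfg.seed,
        "status": "running",
        "stages": {},
        "outputs": [],
    }

    def _declare(name: str, df_or_obj, writer):
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    try:
        t0 = time.time()
        geno, pheno, meta = _load_data(cfg)
        manifest["stages"]["load"] = {"seconds": round(time.time() - t0, 2),
                                      "mode": meta["mode"],
                                      "n_lines": geno.n_lines,
                                      "n_markers": geno.n_markers}

        t0 = time.time()
        clean, report = run_qc(geno, QCConfig(**cfg.qc))
        _declare("qc_report.json", report, lambda p: io.write_qc_report(report, p))
        manifest["stages"]["qc"] = {"seconds": round(time.time() - t0, 2),
                                    **report.as_dict()}

        t0 = time.time()
        vtab = variance_table(pheno)
        _declare("variance_components.csv", vtab,
                 lambda p: vtab.to_csv(p, index=False))
        h2_table = {(row.trait, row.regime): row.H2 for row in vtab.itertuples()}
        corr = trait_correlations(pheno)
        for key, mat in corr.items():
            if isinstance(mat, pd.DataFrame):
                _declare(f"correlations_{key}.csv", mat, lambda p, m=mat: m.to_csv(p))
        manifest["stages"]["quantgen"] = {"seconds": round(time.time() - t0, 2)}

        t0 = time.time()
        results = _evaluate(cfg, clean, pheno, h2_table, manifest["outputs"])
        tables = summarize(results)
        _declare("results_long.csv", tables["long"],
                 lambda p: tables["long"].to_csv(p, index=False))
        for (scheme, regime, metric), wide in tables["wide"].items():
            safe = regime.replace("->", "_to_")
            _declare(f"table_{scheme}_{safe}_{metric}.csv", wide,
                     lambda p, w=wide: w.to_csv(p))
        if "means" in tables and not tables["means"].empty:
            _declare("model_means.csv", tables["means"],
                     lambda p: tables["means"].to_csv(p, index=False))
        manifest["stages"]["evaluate"] = {
            "seconds": round(time.time() - t0, 2), "n_results": len(results)}
        manifest["status"] = "ok"
    except Exception as exc:  # noqa: BLE001 - failure cause belongs in the manifest
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["traceback"] = traceback.format_exc()
        raise
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
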