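"""End-to-end orchestration of the four-step drug-target MR study.

Step 1–2: per gene, simulate (or load) a cis region, select and harmonize
instruments, run GLS-IVW MR and colocalization, and scan a phenome of
outcomes with single-variant Wald MR.  Step 3: genetic-mimicry concordance
over a metabolite panel plus functional-variant-restricted MR.  Step 4:
protein-truncating-variant carrier studies pooled by fixed-effect IVW per
allele and per mmol/L TG.

The run is fully seeded: the master seed spawns independent per-stage
sub-seeds, and an identical config + seed reproduces the results bundle
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import coloc as coloc_mod
from . import mr
from .concordance import meta_fixed, mimicry
from .instruments import SelectionParams, filter_functional_variants, select_cis
from .phewas import build_scheme, phewas_scan
from .simulate import SimConfig, simulate_metabolite_panel, simulate_ptv_study, simulate_region
from .sumstats import harmonize

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "steps": [1, 2, 3, 4],
    "seed": 0,
    "selection": {"p_threshold": 5e-8, "clump_r2": 0.10},
    "coloc_priors": [1e-4, 1e-4, 1e-5],
    # Example design shape: three protein-lowering drug targets plus the two
    # lipase positive/negative controls.  theta is the outcome log-OR per
    # s.d. *higher* protein, so lowering a positive-theta target protects.
    "genes": [
        {"name": "ANGPTL3", "sim": {"theta": 0.02}},
        {"name": "ANGPTL4", "sim": {"theta": 0.56}},
        {"name": "APOC3", "sim": {"theta": 0.11}},
        {"name": "LPL", "sim": {"theta": 0.37}},
        {"name": "LIPG", "sim": {"theta": -0.32}},
    ],
    "phewas": {"n_phenotypes": 40, "n_true_effects": 3, "scheme": "phenome_wide"},
    "step3": {"n_traits": 167, "concordance_rho": 0.91},
    "step4": {
        "studies": [
            {"study": "DiscoveryExomes", "n_carriers": 1200, "n_noncarriers": 120_000},
            {"study": "Biobank", "n_carriers": 900, "n_noncarriers": 180_000},
            {"study": "CaseControl", "n_carriers": 300, "n_noncarriers": 40_000},
        ],
        "tg_shift": -0.81,
        "or_per_allele": 0.71,
    },
}


def load_config(path: str | Path | None) -> dict:
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(config, user)
    steps = set(config["steps"])
    if not steps <= {1, 2, 3, 4}:
        raise ValueError(f"steps must be a subset of {{1,2,3,4}}, got {sorted(steps)}")
    return config


def _deep_update(base: dict, update: dict) -> None:
    for key, value in update.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def _sub_seed(master: int, label: str) -> int:
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.10g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a replay hint."""

    def __init__(self, stage: str, replay: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed ({cause}); replay with: {replay}")
        self.stage = stage
        self.replay = replay


def run(config: dict, outdir: str | Path) -> dict:
    """Execute the configured steps and write the report bundle.

    Returns the machine-readable results dict (also written to
    ``results.json``); per-step tabular reports are written as TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    steps = sorted(set(config["steps"]))
    results: dict[str, Any] = {"seed": seed, "steps": steps}
    log_lines: list[str] = []

    def stage(name: str, fn, replay: str):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, replay, exc) from exc
        elapsed = time.perf_counter() - t0
        payload = hashlib.sha256(
            json.dumps(_round_floats(out), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        log_lines.append(
            f"stage={name} seed={seed} hash={payload} elapsed={elapsed:.2f}s"
        )
        return out

    if 1 in steps or 2 in steps:
        results["step1_2"] = stage(
            "step1_2_mr_coloc", lambda: _run_mr_coloc(config, seed, outdir),
            "dtmr run --steps 1,2",
        )
    if 2 in steps:
        results["phewas"] = stage(
            "step2_phewas", lambda: _run_phewas(config, seed, outdir),
            "dtmr run --steps 2",
        )
    if 3 in steps:
        results["step3"] = stage(
            "step3_mimicry", lambda: _run_step3(config, seed, outdir),
            "dtmr run --steps 3",
        )
    if 4 in steps:
        results["step4"] = stage(
            "step4_ptv_meta", lambda: _run_step4(config, seed, outdir),
            "dtmr run --steps 4",
        )

    (outdir / "results.json").write_text(
        json.dumps(_round_floats(results), indent=1, sort_keys=True) + "\n"
    )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _gene_sim_config(config: dict, gene_cfg: dict, seed: int) -> SimConfig:
    sim = dict(gene_cfg.get("sim", {}))
    sim.setdefault("gene", gene_cfg["name"])
    sim["seed"] = _sub_seed(seed, f"region:{gene_cfg['name']}")
    return SimConfig.from_dict(sim)


def _run_mr_coloc(config: dict, seed: int, outdir: Path) -> list[dict]:
    sel = SelectionParams(**config["selection"])
    priors = tuple(config["coloc_priors"])
    rows = []
    for gene_cfg in config["genes"]:
        sim = _gene_sim_config(config, gene_cfg, seed)
        exposure, outcome, ld, truth = simulate_region(sim)
        region = sim.region()
        instruments = select_cis(exposure, region, ld, sel)
        row: dict[str, Any] = {"gene": gene_cfg["name"], "theta_true": sim.theta}
        if instruments.empty:
            row.update({"n_snps": 0, "note": "Zero SNPs"})
            rows.append(row)
            continue
        harm = harmonize(exposure, outcome)
        instruments = instruments.attach_outcome(harm)
        if instruments.n_snps == 1:
            result = mr.wald_ratio(
                float(instruments.exposure_beta[0]), float(instruments.exposure_se[0]),
                float(instruments.outcome_beta[0]), float(instruments.outcome_se[0]),
            )
        else:
            result = mr.gls_ivw(instruments)
        lowered = mr.orient_to_lowering(result)
        cres = coloc_mod.colocalize(
            exposure, outcome, region, priors=priors,
            w1=coloc_mod.W_QUANTITATIVE, w2=coloc_mod.W_BINARY,
        )
        row.update(result.summary_row())
        row["estimate_per_lowered_sd"] = lowered.estimate
        row["or_per_lowered_sd"] = lowered.odds_ratio
        row.update(cres.summary_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "step12_mr_coloc.tsv", sep="\t", index=False)
    return rows


def _run_phewas(config: dict, seed: int, outdir: Path) -> dict:
    """Single-variant phenome scan over simulated outcome phenotypes."""
    pw = config["phewas"]
    gene_cfg = config["genes"][0]
    sim = _gene_sim_config(config, gene_cfg, seed)
    exposure, _, _, truth = simulate_region(sim)
    instrument = min(exposure, key=lambda r: r.pvalue)

    rng = np.random.default_rng(_sub_seed(seed, "phewas"))
    n_pheno = int(pw["n_phenotypes"])
    n_true = int(pw.get("n_true_effects", 0))
    scheme = build_scheme(pw.get("scheme", "phenome_wide"))
    outcomes = {}
    from dataclasses import replace

    for j in range(n_pheno):
        theta_j = -0.4 if j < n_true else 0.0
        se_j = 0.05
        beta_j = theta_j * instrument.beta + rng.normal(0.0, se_j)
        p_j = float(np.clip(2.0 * stats.norm.sf(abs(beta_j / se_j)), 5e-324, 1.0))
        rec = replace(
            instrument, trait=f"PHENO_{j:03d}", beta=beta_j, se=se_j, pvalue=p_j, unit="log_or"
        )
        outcomes[f"PHENO_{j:03d}"] = (f"simulated phenotype {j}", "A", [rec])

    rows, not_testable = phewas_scan(instrument, outcomes, scheme)
    df = pd.DataFrame([r.summary_row() for r in rows])
    df.to_csv(outdir / "step2_phewas.tsv", sep="\t", index=False)
    return {
        "gene": gene_cfg["name"],
        "instrument": instrument.variant.id,
        "m": scheme.m,
        "n_tested": len(rows),
        "n_not_testable": len(not_testable),
        "n_pass": int(sum(r.pass_threshold for r in rows)),
        "top": [r.summary_row() for r in rows[:5]],
    }


def _run_step3(config: dict, seed: int, outdir: Path) -> dict:
    s3 = config["step3"]
    out: dict[str, Any] = {"mimicry": [], "functional_mr": []}
    mim_rows, fun_rows = [], []
    for gene_cfg in config["genes"][:3]:
        gene = gene_cfg["name"]
        panel = simulate_metabolite_panel(
            n_traits=int(s3["n_traits"]),
            concordance_rho=float(s3["concordance_rho"]),
            seed=_sub_seed(seed, f"panel:{gene}"),
        )
        mres = mimicry(panel.cv_effects, panel.ptv_effects)
        mim_rows.append(
            {"gene": gene, "n_traits": mres.n_traits, "r2": mres.r2,
             "slope": mres.slope, "intercept": mres.intercept}
        )

        sim = _gene_sim_config(config, gene_cfg, seed)
        exposure, outcome, ld, _ = simulate_region(sim)
        functional = filter_functional_variants(exposure, p_relaxed=0.01)
        if functional:
            harm = harmonize(functional, outcome)
            bx = np.array([p.exposure.beta for p in harm.pairs])
            sx = np.array([p.exposure.se for p in harm.pairs])
            by = np.array([p.outcome.beta for p in harm.pairs])
            sy = np.array([p.outcome.se for p in harm.pairs])
            model = "random" if len(bx) > 1 else "fixed"
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                res = mr.ivw((bx, sx, by, sy), effects_model=model)
            fun_rows.append({"gene": gene, **res.summary_row()})
    out["mimicry"] = mim_rows
    out["functional_mr"] = fun_rows
    pd.DataFrame(mim_rows).to_csv(outdir / "step3_mimicry.tsv", sep="\t", index=False)
    pd.DataFrame(fun_rows).to_csv(outdir / "step3_functional_mr.tsv", sep="\t", index=False)
    return out


def _run_step4(config: dict, seed: int, outdir: Path) -> dict:
    s4 = config["step4"]
    studies = [
        simulate_ptv_study(
            n_carriers=int(s["n_carriers"]),
            n_noncarriers=int(s["n_noncarriers"]),
            tg_shift=float(s.get("tg_shift", s4["tg_shift"])),
            or_per_allele=float(s.get("or_per_allele", s4["or_per_allele"])),
            seed=_sub_seed(seed, f"ptv:{s['study']}"),
            study=s["study"],
        )
        for s in s4["studies"]
    ]
    records = [s.record for s in studies]
    per_allele = meta_fixed(records, scale="per_allele")
    per_tg = meta_fixed(records, scale="per_mmol_tg")
    rows = [
        {"study": s.record.study, "log_or": s.record.log_or_per_allele,
         "se": s.record.se, "tg_effect": s.record.tg_effect_per_allele,
         "low_count_warning": s.low_count_warning}
        for s in studies
    ]
    rows.append({"study": "POOLED (per allele)", **per_allele.summary_row()})
    rows.append({"study": "POOLED (per mmol/L TG)", **per_tg.summary_row()})
    pd.DataFrame(rows).to_csv(outdir / "step4_ptv_meta.tsv", sep="\t", index=False)
    return {
        "per_allele": per_allele.summary_row(),
        "per_mmol_tg": per_tg.summary_row(),
        "true_or_per_allele": float(s4["or_per_allele"]),
        "studies": rows[:-2],
    }
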