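"""End-to-end pipeline runs from a single YAML config.

Stages execute in dependency order — simulate (optional) -> evidence -> fit
-> cross-validation (optional) -> permutation test (optional) -> staging ->
plots — and all randomness flows from one root seed via named substreams, so
re-running the same config reproduces every numeric artifact byte for byte.
A manifest records input hashes, seeds and per-stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import load_cohort
from .dictionary import build_event_index, load_symptom_dictionary
from .model import MCMCSettings, OrdinalSuStaIn
from .noise import build_evidence, estimate_correct_scoring
from .permtest import permutation_test
from .selection import crossvalidate
from .simulate import SimulationConfig, generate_cohort
from .viz import pdg, pvd_matrix, render_pdg, render_pvd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see the YAML schema in docs)."""

    out_dir: Path
    cohort_path: Path | None = None
    dictionary_path: Path | None = None
    simulate: dict | None = None
    noise: dict = field(default_factory=dict)  # cap, floor
    mcmc: dict = field(default_factory=dict)  # n_iter, burn_in, thinning, ...
    n_subtypes: int = 1
    cv: dict | None = None  # C_range, k_folds
    permtest: dict | None = None  # label, B
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            out_dir=Path(raw.get("out_dir", "ordsustain_run")),
            cohort_path=Path(raw["cohort"]) if "cohort" in raw else None,
            dictionary_path=Path(raw["dictionary"]) if "dictionary" in raw else None,
            simulate=raw.get("simulate"),
            noise=raw.get("noise", {}),
            mcmc=raw.get("mcmc", {}),
            n_subtypes=int(raw.get("n_subtypes", 1)),
            cv=raw.get("cv"),
            permtest=raw.get("permtest"),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulate is None:
            if self.cohort_path is None or self.dictionary_path is None:
                raise ValueError(
                    "config must give either a 'simulate' block or both "
                    "'cohort' and 'dictionary' paths"
                )
            for p in (self.cohort_path, self.dictionary_path):
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    def mcmc_settings(self) -> MCMCSettings:
        return MCMCSettings(**self.mcmc)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _substream(root: int, name: str) -> int:
    digest = hashlib.sha256(f"{root}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
    }

    try:
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim = SimulationConfig(**sim_kwargs)
            cohort, truth = generate_cohort(sim, seed=_substream(config.seed, "simulate"))
            dictionary = sim.dictionary
            cohort_path = out / "cohort.csv"
            cohort.save(cohort_path)
            (out / "truth.json").write_text(json.dumps(truth.to_dict()) + "\n")
            dict_path = out / "dictionary.json"
            dictionary.save(dict_path)
            manifest["stages"]["simulate"] = {
                "cohort": str(cohort_path),
                "truth": str(out / "truth.json"),
            }
        else:
            dictionary = load_symptom_dictionary(config.dictionary_path)
            cohort = load_cohort(config.cohort_path, dictionary)
            manifest["inputs"] = {
                "cohort": _sha256(Path(config.cohort_path)),
                "dictionary": _sha256(Path(config.dictionary_path)),
            }
    except Exception:
        logger.exception("stage failed: data")
        raise

    try:
        noise = estimate_correct_scoring(
            cohort,
            dictionary,
            cap=float(config.noise.get("cap", 0.95)),
            floor=float(config.noise.get("floor", 0.5)),
        )
        evidence = build_evidence(cohort, dictionary, noise)
        index = build_event_index(dictionary)
        manifest["stages"]["evidence"] = {
            "n_cases": evidence.n_subjects,
            "n_events": index.n_events,
            "p_correct": noise.p_correct,
        }
    except Exception:
        logger.exception("stage failed: evidence")
        raise

    settings = config.mcmc_settings()
    try:
        model = OrdinalSuStaIn(evidence, index, n_subtypes=config.n_subtypes)
        model.dictionary = dictionary
        fit = model.fit(seed=_substream(config.seed, "fit"), settings=settings)
        fit_path = out / "fit.json"
        fit.save(fit_path)
        manifest["stages"]["fit"] = {
            "path": str(fit_path),
            "loglik": fit.loglik,
            "n_subtypes": fit.n_subtypes,
        }
    except Exception:
        logger.exception("stage failed: fit")
        raise

    if config.cv is not None:
        try:
            cv = crossvalidate(
                model.engine,
                C_range=list(config.cv.get("C_range", [1, 2])),
                k_folds=int(config.cv.get("k_folds", 10)),
                seed=_substream(config.seed, "cv"),
                settings=settings.scaled(float(config.cv.get("budget_fraction", 0.2))),
            )
            cv.oofll_frame().to_csv(out / "cv_oofll.csv", index=False)
            cv.cvic_frame().to_csv(out / "cv_cvic.csv", index=False)
            logger.info("cross-validation chose C=%d", cv.chosen_C)
            manifest["stages"]["cv"] = {"chosen_C": cv.chosen_C, "cvic": cv.cvic}
        except Exception:
            logger.exception("stage failed: cv")
            raise

    if config.permtest is not None:
        try:
            label = config.permtest["label"]
            case_labels = cohort.cases().strata[label].to_numpy()
            result = permutation_test(
                model.engine,
                case_labels,
                B=int(config.permtest.get("B", 1000)),
                seed=_substream(config.seed, "permtest"),
                settings=settings.scaled(
                    float(config.permtest.get("budget_fraction", 0.1))
                ),
            )
            (out / "permtest.json").write_text(json.dumps(result.to_dict()) + "\n")
            manifest["stages"]["permtest"] = {
                "label": label,
                "p_value": result.p_value,
                "p_is_bound": result.p_is_bound,
            }
        except Exception:
            logger.exception("stage failed: permtest")
            raise

    try:
        assign = fit.stage_assignments()
        staging_path = out / "staging.csv"
        assign.to_frame().to_csv(staging_path, index=False)
        manifest["stages"]["stage"] = {
            "path": str(staging_path),
            "n_unclassifiable": int(np.sum(~assign.classifiable)),
        }
    except Exception:
        logger.exception("stage failed: stage")
        raise

    try:
        plots = []
        for c in range(fit.n_subtypes):
            p = out / f"pvd_subtype{c + 1}.svg"
            render_pvd(pvd_matrix(fit, c), p, title=f"subtype {c + 1}")
            plots.append(str(p))
        if fit.n_subtypes >= 2:
            p = out / "pdg_subtype1_vs_2.svg"
            render_pdg(pdg(fit, fit, 0, 1), p, "subtype 1", "subtype 2")
            plots.append(str(p))
        manifest["stages"]["plots"] = plots
    except Exception:
        logger.exception("stage failed: plots")
        raise

    manifest["outputs"] = {
        p: _sha256(Path(p))
        for stage in manifest["stages"].values()
        if isinstance(stage, dict)
        for p in ([stage.get("path")] if stage.get("path") else [])
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
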