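"""Pipeline orchestration: run configuration, stage execution, fixture checks.

A run executes the requested stages in dependency order and writes a
machine-readable JSON summary plus a human-readable log.  Every output
carries the package version and a hash of the configuration, so runs are
traceable; identical config + seed gives byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError

logger = logging.getLogger("fukomys")

KNOWN_STAGES = ("stats", "distances", "parsimony", "likelihood", "dec", "shape")
DEFAULT_PARAMS = {
    "distance_alpha": 1.4964,     # gamma shape for TN93+G distances
    "ml_gamma": 0.453,            # gamma shape of the ML model
    "ml_p_inv": 0.52275,          # invariant-site proportion
    "ml_categories": 5,
    "dec_model": "stratified",
}


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    out_dir: str = "results/run"
    fasta: str | None = None
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.stages:
            raise ConfigError("stage list is empty")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        unknown_params = set(self.params) - set(DEFAULT_PARAMS)
        if unknown_params:
            raise ConfigError(f"unknown parameters: {sorted(unknown_params)}")
        if self.fasta is not None and not Path(self.fasta).exists():
            raise ConfigError(f"input file not found: {self.fasta}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = json.load(fh)
        known = {"stages", "seed", "out_dir", "fasta", "params", "log_level"}
        unknown = set(cfg) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        params = dict(DEFAULT_PARAMS)
        params.update(cfg.get("params", {}))
        return cls(
            stages=cfg["stages"],
            seed=cfg.get("seed", 0),
            out_dir=cfg.get("out_dir", "results/run"),
            fasta=cfg.get("fasta"),
            params=params,
            log_level=cfg.get("log_level", "INFO"),
        )

    def hash(self) -> str:
        payload = json.dumps(
            {
                "stages": self.stages,
                "seed": self.seed,
                "fasta": self.fasta,
                "params": self.params,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_stats(config: RunConfig) -> dict:
    from .specimens import (
        adult_mask, dimorphism_t_test, group_summary, load_specimen_table,
    )

    df = load_specimen_table()
    han = group_summary(df, adult_mask(df, "F. hanangensis", "exclude_class1"))
    liv = group_summary(df, adult_mask(df, "F. livingstoni", "class2_plus"))
    t = dimorphism_t_test(df)
    return {
        "hanangensis_adult": {
            "n": han.n, "mean_g": round(han.mean, 4),
            "sem_g": round(han.sem, 4), "range_g": [han.minimum, han.maximum],
        },
        "livingstoni_adult": {
            "n": liv.n, "mean_g": round(liv.mean, 4), "sem_g": round(liv.sem, 4),
        },
        "dimorphism_t_test": {
            "t": round(t.value, 4), "df": t.df[0], "p": round(t.p_value, 4),
        },
    }


def _default_alignment(config: RunConfig):
    from .alignment import read_fasta
    from .likelihood import SubstitutionModel
    from .simulate import sim_sequences, sim_tree

    if config.fasta:
        return read_fasta(config.fasta)
    tree = sim_tree(8, root_age=1.0, seed=config.seed)
    for nd in tree.preorder_node_iter():
        if nd.parent_node:
            nd.edge.length = (nd.edge.length or 0.0) * 0.1
    model = SubstitutionModel(
        freqs=np.array([0.3, 0.25, 0.13, 0.32]),
        kappa1=4.0, kappa2=6.0,
        alpha=config.params["ml_gamma"],
        p_inv=config.params["ml_p_inv"],
        n_categories=config.params["ml_categories"],
    )
    return sim_sequences(tree, model, length=1140, seed=config.seed + 1)


def _stage_distances(config: RunConfig, out_dir: Path) -> dict:
    from .alignment import collapse_haplotypes
    from .distances import pairwise_distance_matrix

    a = _default_alignment(config)
    hap = collapse_haplotypes(a)
    dm_p = pairwise_distance_matrix(a, model="p")
    dm_g = pairwise_distance_matrix(
        a, model="tn93_gamma", alpha=config.params["distance_alpha"]
    )
    dm_p.to_tsv(out_dir / "distances_p.tsv")
    dm_g.to_tsv(out_dir / "distances_tn93g.tsv")
    off = ~np.eye(a.n, dtype=bool)
    return {
        "n_sequences": a.n,
        "n_haplotypes": hap.n_haplotypes(),
        "mean_p_distance": round(float(dm_p.matrix[off].mean()), 6),
        "mean_tn93g_distance": round(float(dm_g.matrix[off].mean()), 6),
    }


def _stage_parsimony(config: RunConfig, out_dir: Path) -> dict:
    from .parsimony import classify_sites, fitch_length, parsimony_search

    a = _default_alignment(config)
    const, inf, uninf = classify_sites(a)
    search = parsimony_search(a, seed=config.seed)
    res = fitch_length(search.trees[0], a)
    (out_dir / "mp_trees.nwk").write_text("\n".join(search.newicks) + "\n")
    return {
        "sites": {"constant": const, "informative": inf, "uninformative": uninf},
        "tree_length": search.length,
        "n_minimal_trees": len(search.trees),
        "ci": round(res.ci, 4),
        "ri": round(res.ri, 4),
    }


def _stage_likelihood(config: RunConfig, out_dir: Path) -> dict:
    from .likelihood import SubstitutionModel, nni_search
    from .trees import write_newick

    a = _default_alignment(config)
    model = SubstitutionModel.from_alignment(
        a,
        kappa1=4.0, kappa2=6.0,
        alpha=config.params["ml_gamma"],
        p_inv=config.params["ml_p_inv"],
        n_categories=config.params["ml_categories"],
    )
    tree, lnl = nni_search(a, model, seed=config.seed)
    (out_dir / "ml_tree.nwk").write_text(write_newick(tree) + "\n")
    return {"log_likelihood": round(lnl, 4)}


def _stage_dec(config: RunConfig, out_dir: Path) -> dict:
    from .dec import compare_models, fit_dec
    from .fixtures import load_chronogram, load_dec_spec, load_tip_ranges

    chrono = load_chronogram()
    ranges = load_tip_ranges()
    fits = []
    for name in ("m0", "m1", "stratified"):
        spec = load_dec_spec(name)
        fits.append(
            fit_dec(chrono, ranges, spec, model_name=name, seed=config.seed)
        )
    table, diffs = compare_models(fits)
    table.to_csv(out_dir / "dec_models.tsv", sep="\t", index=False)
    return {
        f.model_name: {
            "lnL": round(f.loglik, 4),
            "dispersal": float(f.d),
            "extinction": float(f.e),
        }
        for f in fits
    }


def _stage_shape(config: RunConfig, out_dir: Path) -> dict:
    from .shape import gpa, relative_warps
    from .simulate import sim_landmarks

    rng = np.random.default_rng(config.seed)
    mean = rng.normal(0, 1, size=(15, 2))
    disp = np.zeros((15, 2))
    disp[:5, 0] = 0.15
    configs = sim_landmarks(
        mean, {"A": 12, "B": 12}, {"B": disp}, noise_sd=0.03,
        seed=config.seed, n_replicates=3,
    )
    aligned = gpa(configs)
    warps = relative_warps(aligned)
    return {
        "n_configs": aligned.n,
        "rw1_variance_fraction": round(float(warps.variance_fractions[0]), 4),
    }


_STAGE_FUNCS = {
    "stats": lambda cfg, out: _stage_stats(cfg),
    "distances": _stage_distances,
    "parsimony": _stage_parsimony,
    "likelihood": _stage_likelihood,
    "dec": _stage_dec,
    "shape": _stage_shape,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write ``summary.json`` + log."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    summary = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
    }
    order = [s for s in KNOWN_STAGES if s in config.stages]
    for stage in order:
        logger.info("running stage %s (seed=%d)", stage, config.seed)
        try:
            summary["stages"][stage] = _STAGE_FUNCS[stage](config, out_dir)
        except Exception as exc:
            raise RuntimeError(
                f"stage {stage!r} failed on inputs "
                f"(fasta={config.fasta!r}, seed={config.seed}); reproduce with "
                f"`fukomys run --stages {stage} --seed {config.seed}`: {exc}"
            ) from exc
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("summary written to %s", path)
    return summary


def validate_fixture_tables() -> dict:
    """Integrity checks of the packaged collection table."""
    from .specimens import load_specimen_table

    df = load_specimen_table()
    report = {"passed": True, "checks": []}

    def check(name: str, ok: bool, detail: str = "") -> None:
        report["checks"].append({"check": name, "ok": bool(ok), "detail": detail})
        if not ok:
            report["passed"] = False

    expected_counts = {"F. hanangensis": 40, "F. livingstoni": 6, "F. whytei": 3}
    counts = df["species"].value_counts().to_dict()
    for sp, n in expected_counts.items():
        check(
            f"row count {sp}", counts.get(sp, 0) == n,
            f"expected {n}, found {counts.get(sp, 0)}",
        )
    weights = df["body_weight_g"].dropna()
    check("weights positive", bool((weights > 0).all()))
    check("weights plausible (< 500 g)", bool((weights < 500).all()))
    alts = df["altitude_m"].dropna()
    check("altitudes in 500-3000 m", bool(((alts > 500) & (alts < 3000)).all()))
    ages = df["age_class"].dropna()
    check("age classes in 1-4", bool(ages.isin([1, 2, 3, 4]).all()))
    hap = df.dropna(subset=["haplotype"])
    consistent = (
        hap.groupby("haplotype")["species"].nunique().le(1).all()
    )
    check("haplotype labels species-consistent", bool(consistent))
    return report
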