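"""End-to-end orchestration: preprocess, correlate, select thresholds by
self-consistency, build density-matched networks, summarize and evaluate.

Every stage is a pure function of (inputs, config, seed); the run manifest
records the config, seeds, library versions and SHA-256 hashes of every
written file, so equal manifests imply byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .bioeval import DEFAULT_PRIOR, EvaluationReport, evaluation_report
from .consistency import ConsistencyProfile, consistency_profile, select_threshold
from .correlations import METHODS, compute_correlation
from .dataio import (
    ExpressionMatrix,
    InteractionScoreTable,
    read_expression_matrix,
    read_interaction_scores,
    write_correlation_matrix,
    write_edge_list,
    write_expression_matrix,
)
from .netbuild import UnweightedNetwork, threshold_for_density, threshold_network, topology_summary
from .preprocess import preprocess

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "METHOD_ABBREV"]

log = logging.getLogger("sdcornet")

METHOD_ABBREV = {
    "signed_distance": "S",
    "pearson": "P",
    "spearman": "R",
    "mutual_information": "I",
    "distance": "D",
}


@dataclass
class RunConfig:
    expression_path: str | None = None
    interaction_path: str | None = None
    methods: tuple[str, ...] = ("signed_distance", "pearson", "mutual_information")
    mask_fraction: float = 0.2
    theta_min: float = 0.0
    theta_max: float = 0.99
    theta_step: float = 0.01
    n_repetitions: int = 25
    seed: int = 0
    mi_bins: int | None = None
    n_random_networks: int = 30
    string_prior: float = DEFAULT_PRIOR
    dedupe_density_tol: float | None = None
    save_correlation_matrices: bool = False
    output_dir: str = "sdcornet_run"

    def validate(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if not self.methods:
            raise ValueError("no methods requested")
        if not (0 <= self.mask_fraction < 1):
            raise ValueError("mask_fraction must be in [0, 1)")
        if self.theta_step <= 0 or self.theta_max < self.theta_min:
            raise ValueError("invalid theta grid")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")

    @property
    def thetas(self) -> np.ndarray:
        n = int(round((self.theta_max - self.theta_min) / self.theta_step)) + 1
        return np.round(self.theta_min + self.theta_step * np.arange(n), 10)


@dataclass
class PipelineResult:
    output_dir: Path
    profiles: dict[str, ConsistencyProfile]
    thresholds: dict[str, tuple[float, float, float]]
    networks: dict[str, UnweightedNetwork]
    topology: dict[str, dict]
    evaluation: EvaluationReport | None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_profile(profile: ConsistencyProfile, prefix: Path) -> list[Path]:
    tsv = prefix.with_suffix(".tsv")
    with open(tsv, "wt") as fh:
        fh.write("theta\ts\tdensity\tscore\n")
        for t, s, d, sc in zip(
            profile.thetas, profile.s_values, profile.densities, profile.scores
        ):
            fh.write(f"{t:.6g}\t{s:.10g}\t{d:.10g}\t{sc:.10g}\n")
    theta, score, density = select_threshold(profile)
    js = prefix.with_suffix(".json")
    with open(js, "wt") as fh:
        json.dump(
            {
                "method": profile.method,
                "theta_star": theta,
                "score": score,
                "density": density,
                "n_repetitions": profile.n_repetitions,
                "seed": profile.seed,
            },
            fh,
            indent=2,
        )
    return [tsv, js]


def run_pipeline(
    config: RunConfig,
    expression: ExpressionMatrix | None = None,
    interactions: InteractionScoreTable | None = None,
) -> PipelineResult:
    """Run the full pipeline and write all artifacts under ``output_dir``.

    ``expression``/``interactions`` may be passed directly (e.g. synthetic
    data); otherwise they are read from the paths in the config.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if expression is None:
        if config.expression_path is None:
            raise ValueError("no expression matrix given")
        log.info("loading expression matrix from %s", config.expression_path)
        expression = read_expression_matrix(config.expression_path)
    if interactions is None and config.interaction_path is not None:
        log.info("loading interaction scores from %s", config.interaction_path)
        interactions = read_interaction_scores(config.interaction_path)

    log.info(
        "stage A: preprocessing %d genes x %d samples (mask fraction %.2f)",
        expression.n_genes, expression.n_samples, config.mask_fraction,
    )
    mstar = preprocess(expression, config.mask_fraction)
    mstar_path = out / "Mstar.tsv"
    write_expression_matrix(mstar, mstar_path)
    written.append(mstar_path)

    thetas = config.thetas
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.methods) + 1)

    matrices: dict[str, np.ndarray] = {}
    profiles: dict[str, ConsistencyProfile] = {}
    thresholds: dict[str, tuple[float, float, float]] = {}
    networks: dict[str, UnweightedNetwork] = {}

    for k, method in enumerate(config.methods):
        abbrev = METHOD_ABBREV[method]
        log.info("stages B-E: %s correlation matrix", method)
        C = compute_correlation(mstar, method, config.mi_bins)
        matrices[method] = C
        if config.save_correlation_matrices:
            cpath = out / f"correlation_{method}.tsv.gz"
            write_correlation_matrix(C, cpath)
            written.append(cpath)
        log.info(
            "stage F: consistency profile for %s (%d thetas, %d repetitions)",
            method, thetas.size, config.n_repetitions,
        )
        profile = consistency_profile(
            expression,
            method=method,
            thetas=thetas,
            n_repetitions=config.n_repetitions,
            seed=children[k],
            mask_fraction=config.mask_fraction,
            mi_bins=config.mi_bins,
        )
        profile.seed = config.seed
        profiles[method] = profile
        written.extend(_write_profile(profile, out / f"profile_{abbrev}"))
        theta, score, density = select_threshold(profile)
        thresholds[method] = (theta, score, density)
        log.info("  %s: theta*=%.4g score=%.4g density=%.4g", method, theta, score, density)
        net = threshold_network(C, theta)
        net.provenance["native"] = True
        networks[f"N{abbrev}(d{abbrev})"] = net

    # density matching: every method gets a network at every native density
    native_densities = {m: thresholds[m][2] for m in config.methods}
    matched = dict(native_densities)
    if config.dedupe_density_tol is not None:
        kept: dict[str, float] = {}
        for m, d in native_densities.items():
            if all(abs(d - d2) > config.dedupe_density_tol for d2 in kept.values()):
                kept[m] = d
        matched = kept
    for target_method, d in matched.items():
        if d <= 0:
            log.warning("native density for %s is 0; skipping matched networks", target_method)
            continue
        for method in config.methods:
            if method == target_method:
                continue
            abbrev = METHOD_ABBREV[method]
            tgt = METHOD_ABBREV[target_method]
            theta, achieved = threshold_for_density(matrices[method], d)
            net = threshold_network(matrices[method], theta)
            net.provenance["matched_to"] = target_method
            networks[f"N{abbrev}(d{tgt})"] = net

    for name, net in networks.items():
        path = out / f"network_{name}.tsv"
        write_edge_list(net, path)
        written.append(path)

    topology = {name: topology_summary(net).as_dict() for name, net in networks.items()}
    topo_path = out / "topology.json"
    with open(topo_path, "wt") as fh:
        json.dump(topology, fh, indent=2)
    written.append(topo_path)

    evaluation = None
    if interactions is not None:
        log.info("evaluating %d networks against interaction scores", len(networks))
        scored = {n: net for n, net in networks.items() if net.n_edges > 0}
        evaluation = evaluation_report(
            scored,
            interactions,
            rng=np.random.default_rng(children[-1]),
            n_networks=config.n_random_networks,
            prior=config.string_prior,
        )
        eval_tsv = out / "evaluation.tsv"
        evaluation.to_frame().to_csv(eval_tsv, sep="\t", index=False)
        written.append(eval_tsv)

    cfg_dict = asdict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "sdcornet_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "thresholds": {m: list(v) for m, v in thresholds.items()},
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2)

    return PipelineResult(out, profiles, thresholds, networks, topology, evaluation, manifest)
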