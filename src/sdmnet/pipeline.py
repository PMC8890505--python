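"""End-to-end orchestration of the SDMN analysis.

A single YAML config drives the whole chain: data (synthetic generation or
user-supplied CSVs) -> contest statistics (gated tests, PCA, perMANOVA) ->
per-region activation tests -> bootstrapped treatment networks ->
edge-weight comparisons -> eigencentrality hubs and cross-sex hub
intersections.  Every stage writes CSV outputs into the run directory and
the run is summarized in a JSON manifest carrying the config hash, seeds
and library versions.  Completed stages of a previous run with the same
config hash are skipped on rerun.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activation import kruskal_fdr, validate_activation_table
from .catalog import BEHAVIORS, CONDITIONS, SEXES
from .centrality import eigencentrality, hub_intersection
from .connectivity import ConnectivityConfig, build_all_networks, split_signed
from .ethogram import behavior_pca, permanova, sex_comparison_table, summarize_dyads
from .netstats import balance_analysis, compare_weight_distributions, edge_weight_sample
from .synthetic import ActivationModel, BehaviorModel, generate_activation, generate_dyads

__all__ = ["RunConfig", "run_pipeline", "demo"]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Either ``synthetic`` (generator settings) or ``inputs`` (paths to
    events, dyad-metadata and activation CSVs) must be provided.  The
    global seed propagates to every stochastic stage.
    """

    output_dir: str
    seed: int = 0
    synthetic: dict | None = None
    inputs: dict | None = None
    connectivity: dict = field(default_factory=dict)
    permutations: int = 999
    alpha: float = 0.05
    hubs_k: int = 8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("config needs exactly one of 'synthetic' or 'inputs'")
        if self.inputs is not None:
            for key in ("events_csv", "dyad_meta_csv", "activation_csv"):
                if key not in self.inputs:
                    raise ValueError(f"inputs config missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise FileNotFoundError(
                        f"input file for {key!r} does not exist: {self.inputs[key]}"
                    )
        ConnectivityConfig(**{**self.connectivity, "seed": self.seed})  # validates

    def config_hash(self) -> str:
        # identifies the analysis, not its destination directory
        payload = asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return path.name


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    manifest_path = outdir / "manifest.json"
    previous: dict = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            old = json.load(fh)
        if old.get("config_hash") == cfg_hash:
            previous = old.get("stages", {})

    manifest: dict = {
        "package": "sdmnet",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage_done(name: str) -> bool:
        info = previous.get(name)
        if not info:
            return False
        return all((outdir / f).exists() for f in info.get("outputs", []))

    def record(name: str, outputs: list[str], **extra) -> None:
        manifest["stages"][name] = {"outputs": outputs, **extra}

    # ---- stage: data -------------------------------------------------
    if stage_done("data"):
        manifest["stages"]["data"] = {**previous["data"], "cached": True}
        events = pd.read_csv(outdir / "events.csv")
        summaries = pd.read_csv(outdir / "dyad_summaries.csv")
        activation = pd.read_csv(outdir / "activation.csv")
    else:
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            n_dyads = syn.pop("n_dyads_per_sex", 20)
            group_sizes = syn.pop("group_sizes", None)
            behavior_kwargs = syn.pop("behavior", {})
            activation_kwargs = syn.pop("activation", {})
            if syn:
                raise ValueError(f"unknown synthetic config keys: {sorted(syn)}")
            bmodel = BehaviorModel(seed=config.seed, **behavior_kwargs)
            events, gen_summaries = generate_dyads(bmodel, n_dyads)
            if group_sizes is not None:
                group_sizes = {
                    (s, c): int(n)
                    for (s, c), n in (
                        group_sizes.items()
                        if isinstance(group_sizes, dict)
                        else group_sizes
                    )
                }
                activation_kwargs["group_sizes"] = group_sizes
            amodel = ActivationModel(seed=config.seed + 1, **activation_kwargs)
            activation = generate_activation(amodel)
            meta = gen_summaries[["dyad_id", "sex", "resolution_min"]]
        else:
            events = pd.read_csv(config.inputs["events_csv"])
            meta = pd.read_csv(config.inputs["dyad_meta_csv"])
            activation = pd.read_csv(config.inputs["activation_csv"])
        validate_activation_table(activation)
        summaries = summarize_dyads(events, meta)
        outputs = [
            _write(events, outdir / "events.csv"),
            _write(summaries, outdir / "dyad_summaries.csv"),
            _write(activation, outdir / "activation.csv"),
        ]
        record("data", outputs, n_dyads=len(summaries), n_fish=len(activation))

    # ---- stage: ethogram ---------------------------------------------
    if stage_done("ethogram"):
        manifest["stages"]["ethogram"] = {**previous["ethogram"], "cached": True}
    else:
        tests = sex_comparison_table(summaries, alpha_gate=config.alpha)
        totals = summaries[[f"total_{b}" for b in BEHAVIORS]]
        totals.columns = list(BEHAVIORS)
        pca = behavior_pca(totals)
        loadings = pca.loadings.copy()
        loadings.insert(0, "behavior", loadings.index)
        summary_rows = pd.DataFrame(
            {
                "component": pca.loadings.columns,
                "sdev": pca.sdev,
                "proportion": pca.proportion,
                "cumulative": pca.cumulative,
            }
        )
        scores = pd.DataFrame(
            pca.scores, columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]
        )
        scores.insert(0, "dyad_id", summaries["dyad_id"])
        scores.insert(1, "sex", summaries["sex"])
        perm = permanova(
            np.sqrt(totals.to_numpy(dtype=float)),
            summaries["sex"].to_numpy(),
            n_permutations=config.permutations,
            seed=config.seed,
        )
        perm_df = pd.DataFrame(
            [
                {
                    "pseudo_F": perm.pseudo_f,
                    "pvalue": perm.pvalue,
                    "n_permutations": perm.n_permutations,
                    "ss_between": perm.ss_between,
                    "ss_within": perm.ss_within,
                    "ss_total": perm.ss_total,
                }
            ]
        )
        outputs = [
            _write(tests, outdir / "sex_comparisons.csv"),
            _write(loadings, outdir / "pca_loadings.csv"),
            _write(summary_rows, outdir / "pca_summary.csv"),
            _write(scores, outdir / "pca_scores.csv"),
            _write(perm_df, outdir / "permanova.csv"),
        ]
        record(
            "ethogram",
            outputs,
            permanova_F=perm.pseudo_f,
            permanova_p=perm.pvalue,
        )

    # ---- stage: activation -------------------------------------------
    if stage_done("activation"):
        manifest["stages"]["activation"] = {**previous["activation"], "cached": True}
    else:
        outputs = []
        for sex in SEXES:
            res = kruskal_fdr(activation, sex, alpha=config.alpha)
            outputs.append(_write(res, outdir / f"activation_tests_{sex}.csv"))
        record("activation", outputs)

    # ---- stage: networks ---------------------------------------------
    conn_cfg = ConnectivityConfig(**{**config.connectivity, "seed": config.seed})
    networks = build_all_networks(activation, conn_cfg)
    if stage_done("networks"):
        manifest["stages"]["networks"] = {**previous["networks"], "cached": True}
    else:
        outputs = []
        for (sex, condition), net in networks.items():
            edges = net.edge_list()
            outputs.append(_write(edges, outdir / f"network_{sex}_{condition}_edges.csv"))
            dense = pd.DataFrame(net.weights, index=net.regions, columns=net.regions)
            dense.insert(0, "region", dense.index)
            outputs.append(
                _write(dense, outdir / f"network_{sex}_{condition}_matrix.csv")
            )
        record("networks", outputs, n_networks=len(networks))

    # ---- stage: netstats ---------------------------------------------
    if stage_done("netstats"):
        manifest["stages"]["netstats"] = {**previous["netstats"], "cached": True}
    else:
        rows = []

        def add(result):
            rows.append(
                {
                    "sample_a": result.label_a,
                    "sample_b": result.label_b,
                    "n_a": result.n_a,
                    "n_b": result.n_b,
                    "ks_stat": result.ks_stat,
                    "ks_pvalue": result.ks_pvalue,
                    "mwu_stat": result.mwu_stat,
                    "mwu_pvalue": result.mwu_pvalue,
                    "cohen_d": result.cohen_d,
                    "effect": result.effect_label,
                    "note": result.note,
                }
            )

        for sign in ("positive", "negative"):
            tag = "excitation" if sign == "positive" else "inhibition"
            # between sexes, same condition
            for condition in CONDITIONS:
                key_f, key_m = ("F", condition), ("M", condition)
                if key_f in networks and key_m in networks:
                    a = edge_weight_sample(networks[key_f], sign)
                    b = edge_weight_sample(networks[key_m], sign)
                    if len(a) and len(b):
                        add(
                            compare_weight_distributions(
                                a, b, f"F_{condition}_{tag}", f"M_{condition}_{tag}"
                            )
                        )
            # between conditions, same sex
            for sex in SEXES:
                for i, c1 in enumerate(CONDITIONS):
                    for c2 in CONDITIONS[i + 1 :]:
                        k1, k2 = (sex, c1), (sex, c2)
                        if k1 in networks and k2 in networks:
                            a = edge_weight_sample(networks[k1], sign)
                            b = edge_weight_sample(networks[k2], sign)
                            if len(a) and len(b):
                                add(
                                    compare_weight_distributions(
                                        a, b, f"{sex}_{c1}_{tag}", f"{sex}_{c2}_{tag}"
                                    )
                                )
        for key, net in networks.items():
            add(balance_analysis(split_signed(net)))
        comparisons = pd.DataFrame(rows)
        record("netstats", [_write(comparisons, outdir / "comparisons.csv")])

    # ---- stage: centrality -------------------------------------------
    if stage_done("centrality"):
        manifest["stages"]["centrality"] = {**previous["centrality"], "cached": True}
    else:
        outputs = []
        rankings = {}
        for key, net in networks.items():
            ranking = eigencentrality(net, k=config.hubs_k)
            rankings[key] = ranking
            frame = ranking.to_frame()
            frame.insert(0, "condition", key[1])
            frame.insert(0, "sex", key[0])
            outputs.append(
                _write(frame, outdir / f"centrality_{key[0]}_{key[1]}.csv")
            )
        inter_rows = []
        for condition in CONDITIONS:
            key_f, key_m = ("F", condition), ("M", condition)
            if key_f in rankings and key_m in rankings:
                shared, only_f, only_m = hub_intersection(
                    rankings[key_f], rankings[key_m]
                )
                inter_rows.append(
                    {
                        "condition": condition,
                        "n_shared": len(shared),
                        "shared": " ".join(shared),
                        "only_F": " ".join(only_f),
                        "only_M": " ".join(only_m),
                    }
                )
        intersections = pd.DataFrame(inter_rows)
        outputs.append(_write(intersections, outdir / "hub_intersections.csv"))
        record("centrality", outputs)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def demo(output_dir: str | Path, seed: int = 0) -> dict:
    """Small synthetic end-to-end run (completes in well under a minute)."""
    from .synthetic import CorrelationBlock, PlantedHub

    config = RunConfig(
        output_dir=str(output_dir),
        seed=seed,
        synthetic={
            "n_dyads_per_sex": 20,
            "activation": {
                "blocks": [CorrelationBlock(("Vs", "Hv", "TPp"), 0.8)],
                "hubs": [PlantedHub("PM", ("Dm", "Dl", "Vc", "PPp"), 0.8)],
            },
        },
        permutations=199,
    )
    return run_pipeline(config)
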