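"""Run configuration, bundled parameter presets, and JSON (de)serialization.

Config keys mirror the field's symbol names one-to-one:

==============  ==========================================
symbol          config key
==============  ==========================================
k_g             ``k_g``        gene activation rate
gamma_g         ``gamma_g``    gene deactivation rate
k_m             ``k_m``        transcription rate
gamma_m         ``gamma_m``    mRNA degradation rate
k_p             ``k_p``        translation rate
gamma_p         ``gamma_p``    protein degradation rate
n               ``n_copies``   gene copy number
K, n_H, k_l     ``K``, ``n_H``, ``k_l``  Hill regulation
==============  ==========================================
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .langevin import StepConfig
from .model_core import GeneParams
from .regulation import RegulatedNetworkParams

__all__ = ["RunConfig", "load_config", "dump_config", "preset", "PRESET_NAMES"]

_GENE_KEYS = {"k_g", "gamma_g", "k_m", "gamma_m", "k_p", "gamma_p", "n_copies"}
_REQUIRED_GENE_KEYS = _GENE_KEYS - {"n_copies"}
_NET_KEYS = {"upstream", "downstream", "K", "n_H", "k_l"}
_TOP_KEYS = {
    "gene", "network", "regime", "simulator", "step", "experiment",
    "t_end", "n_points", "sample_dt", "out_dir", "seed", "kg_schedule", "tau",
}
_STEP_KEYS = {"epsilon", "n_critical", "max_halvings", "rng_seed"}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one run bit-for-bit."""

    gene: "GeneParams | None" = None
    network: "RegulatedNetworkParams | None" = None
    regime: "str | None" = None  # auto-classified when None
    simulator: str = "bl"
    step: StepConfig = field(default_factory=StepConfig)
    experiment: "str | None" = None
    t_end: float = 20.0
    n_points: int = 2000
    sample_dt: "float | None" = None
    out_dir: str = "."
    seed: int = 0
    kg_schedule: "tuple[tuple[float, float], ...] | None" = None
    tau: "float | None" = None  # reference step size carried by some presets

    def to_dict(self) -> dict:
        d: dict = {}
        if self.gene is not None:
            d["gene"] = dataclasses.asdict(self.gene)
        if self.network is not None:
            d["network"] = {
                "upstream": dataclasses.asdict(self.network.upstream),
                "downstream": dataclasses.asdict(self.network.downstream),
                "K": self.network.K,
                "n_H": self.network.n_H,
                "k_l": self.network.k_l,
            }
        if self.regime is not None:
            d["regime"] = self.regime
        d["simulator"] = self.simulator
        d["step"] = dataclasses.asdict(self.step)
        if self.experiment is not None:
            d["experiment"] = self.experiment
        d.update(t_end=self.t_end, n_points=self.n_points, out_dir=self.out_dir,
                 seed=self.seed)
        if self.sample_dt is not None:
            d["sample_dt"] = self.sample_dt
        if self.kg_schedule is not None:
            d["kg_schedule"] = [list(pair) for pair in self.kg_schedule]
        if self.tau is not None:
            d["tau"] = self.tau
        return d


def _gene_from_dict(d: dict, where: str) -> GeneParams:
    unknown = set(d) - _GENE_KEYS
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")
    missing = _REQUIRED_GENE_KEYS - set(d)
    if missing:
        raise ValueError(f"missing required rates in {where}: {sorted(missing)}")
    return GeneParams(**d)


def config_from_dict(d: dict) -> RunConfig:
    """Validate a raw mapping into a RunConfig (unknown keys rejected)."""
    if not isinstance(d, dict) or not d:
        raise ValueError(
            f"config must be a non-empty mapping; required: a 'gene' or 'network' "
            f"section with rates {sorted(_REQUIRED_GENE_KEYS)}"
        )
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out: dict = {}
    if "gene" in d:
        out["gene"] = _gene_from_dict(d["gene"], "gene")
    if "network" in d:
        nd = dict(d["network"])
        unknown = set(nd) - _NET_KEYS
        if unknown:
            raise ValueError(f"unknown keys in network: {sorted(unknown)}")
        out["network"] = RegulatedNetworkParams(
            upstream=_gene_from_dict(nd["upstream"], "network.upstream"),
            downstream=_gene_from_dict(nd["downstream"], "network.downstream"),
            K=nd["K"], n_H=nd["n_H"], k_l=nd.get("k_l", 0.0),
        )
    if "gene" not in d and "network" not in d:
        raise ValueError("config needs a 'gene' or 'network' section")
    if "regime" in d:
        allowed = {"mrna_burst", "protein_burst", "both_bursts", "no_burst"}
        if d["regime"] not in allowed:
            raise ValueError(f"unknown regime label {d['regime']!r}; one of {sorted(allowed)}")
        out["regime"] = d["regime"]
    if "step" in d:
        unknown = set(d["step"]) - _STEP_KEYS
        if unknown:
            raise ValueError(f"unknown keys in step: {sorted(unknown)}")
        out["step"] = StepConfig(**d["step"])
    if "kg_schedule" in d:
        out["kg_schedule"] = tuple((float(a), float(b)) for a, b in d["kg_schedule"])
    for key in ("simulator", "experiment", "t_end", "n_points", "sample_dt",
                "out_dir", "seed", "tau"):
        if key in d:
            out[key] = d[key]
    return RunConfig(**out)


def load_config(path: str) -> RunConfig:
    """Load and validate a JSON run configuration."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(
            f"empty config file {path}; required: a 'gene' or 'network' section "
            f"with rates {sorted(_REQUIRED_GENE_KEYS)}"
        )
    return config_from_dict(json.loads(text))


def dump_config(cfg: RunConfig, path: "str | None" = None) -> dict:
    """Serialize a RunConfig; returns the dict, optionally writing JSON."""
    d = cfg.to_dict()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)
    return d


# ---------------------------------------------------------------------------
# bundled presets (figure-caption parameter sets)
# ---------------------------------------------------------------------------

_FIG1_GENE = dict(k_g=5.0, gamma_g=95.0, k_m=200.0, gamma_m=10.0,
                  k_p=100.0, gamma_p=1.0)
_SCAN_UPSTREAM = dict(k_g=5.0, gamma_g=100.0, gamma_m=10.0, gamma_p=1.0)

_PRESETS: dict[str, dict] = {
    # single-gene reference with p_bar=100, b_m=2, b_p=10
    "fig1": {"gene": dict(_FIG1_GENE), "simulator": "bl", "t_end": 20.0},
    # analytic SD-error map parameterization (values carried via 'gene' at the
    # map's fixed point gamma_g=100, gamma_m=10; the map itself rescans them)
    "fig2": {
        "gene": dict(k_g=5.0, gamma_g=100.0, k_m=210.0, gamma_m=10.0,
                     k_p=100.0, gamma_p=1.0),
        "experiment": "error-map-analytic",
    },
    # k_g x b_p scan at fixed k_m=100
    "fig3": {
        "gene": dict(k_g=3.0, gamma_g=100.0, k_m=100.0, gamma_m=10.0,
                     k_p=10.0, gamma_p=1.0),
        "experiment": "grid-fig3",
        "n_points": 2000,
    },
    # b_m x b_p scan at k_g=5 (k_m, k_p back-solved per cell)
    "fig5": {
        "gene": dict(k_g=5.0, gamma_g=100.0, k_m=105.0, gamma_m=10.0,
                     k_p=10.0, gamma_p=1.0),
        "experiment": "grid-fig5",
        "n_points": 2000,
    },
    # repression network; upstream at the scan corner b_m1=1, b_p1=1
    "fig6": {
        "network": {
            "upstream": dict(k_g=5.0, gamma_g=100.0, k_m=105.0, gamma_m=10.0,
                             k_p=10.0, gamma_p=1.0),
            "downstream": dict(k_g=5.0, gamma_g=100.0, k_m=200.0, gamma_m=10.0,
                               k_p=100.0, gamma_p=1.0),
            "K": 200.0, "n_H": 3.0, "k_l": 60.0,
        },
        "experiment": "network-fig6",
        "n_points": 2000,
    },
    # genetic switching dynamics: k_g = 3, raised to 30 on t in [7, 14)
    "fig7": {
        "gene": dict(k_g=3.0, gamma_g=100.0, k_m=200.0, gamma_m=10.0,
                     k_p=100.0, gamma_p=1.0),
        "kg_schedule": [[7.0, 30.0], [14.0, 3.0]],
        "experiment": "dynamics-fig7",
        "t_end": 21.0,
    },
    # negative-production showcase: fig1 rates (b_m*b_p = 20) at tau = 0.03
    "fig8": {"gene": dict(_FIG1_GENE), "tau": 0.03},
    # protein-burst bimodality: k_g = gamma_g = 0.1 gamma_p, gamma_m = 10 gamma_p
    "bimodal": {
        "gene": dict(k_g=0.1, gamma_g=0.1, k_m=20.0, gamma_m=10.0,
                     k_p=100.0, gamma_p=1.0),
        "regime": "protein_burst",
        "t_end": 200.0,
    },
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> RunConfig:
    """Bundled parameter preset by name (see PRESET_NAMES)."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    return config_from_dict(json.loads(json.dumps(_PRESETS[name])))
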