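"""Configuration, scenario fixtures and CSV export.

A :class:`Scenario` is a named, fully-resolved flat parameter set plus a
target ("sweep", "invade", "kin" or "abm").  Defaults reproduce the reference
parameter set used throughout the package's figures-style scenarios
(u_B = 0.3, rho_a = 13.8155, rho_l = 5, lambda_d = 1, lambda_l = 50,
d- = d+ = 5, c- = c+ = 3, truncated-normal intensities with mean 0.5 and
sd 0.1, sigmoid activation); named fixtures apply the documented variations
(slower learning, inter-individual differences, assortment, kin).
Unknown keys and out-of-range values are rejected with the offending key
named.  All outputs are RFC-4180 CSV with a '#'-prefixed metadata header
recording package version, seed and the full parameter set.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .abm import ABMConfig, validate_against_replicator
from .cognitive import CognitiveParams
from .fitness import EnvironmentParams, IntensityModel, PayoffParams
from .invasion import gradient_field, singular_numeric, equilibrium_profile
from .kin import regime_map
from .replicator import SweepGrid, phase_diagram

__all__ = [
    "Scenario",
    "DEFAULTS",
    "FIXTURES",
    "load_config",
    "write_config",
    "run_scenario",
    "scenario_objects",
]

TARGETS = ("sweep", "invade", "kin", "abm")

DEFAULTS: dict[str, object] = {
    # cognition
    "u_B": 0.3,
    "u_D": 0.5,
    "rho_a": 13.8155,
    "rho_l": 5.0,
    "lambda_l": 50.0,
    "gamma": 1.0,
    "gamma_s": 1.0,
    "gamma_a": 1.0,
    "activation_kind": "sigmoid",
    # environment
    "lambda_d": 1.0,
    "t_bar": 0.1,
    "p": 0.05,
    "psi": 0.0,
    "assort_w": 1.0,
    "intensity_kind": "truncnorm",
    "intensity_mean": 0.5,
    "intensity_sd": 0.1,
    # payoffs
    "b": 1.0,
    "d_minus": 5.0,
    "d_plus": 5.0,
    "c_minus": 3.0,
    "c_plus": 3.0,
    # sweep grid
    "t_bar_min": 0.05,
    "t_bar_max": 1.0,
    "n_t_bar": 21,
    "p_min": 0.005,
    "p_max": 0.5,
    "n_p": 21,
    # kin grid
    "r_min": 0.0,
    "r_max": 1.0,
    "n_r": 20,
    "c_ratio_min": 0.25,
    "c_ratio_max": 4.0,
    "n_c_ratio": 20,
    # invasion
    "traits": "u_D",
    "field_n": 0,
    # abm
    "n_agents": 150,
    "generations": 60,
    "steps_per_generation": 400,
    "dt": 0.005,
    "n_replicates": 20,
}

FIXTURES: dict[str, dict[str, object]] = {
    "fig2a": {"target": "sweep"},
    "fig2b": {"target": "sweep", "lambda_l": 10.0},
    "fig2c": {"target": "sweep", "psi": 0.5},
    "fig2d": {"target": "sweep", "psi": 0.5, "assort_w": 2.0},
    "fig3": {"target": "invade", "traits": "u_D", "field_n": 13},
    "fig4": {"target": "kin"},
    "abm-validate": {"target": "abm"},
}


@dataclass(frozen=True)
class Scenario:
    name: str
    target: str
    params: dict
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        unknown = set(self.params) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        missing = set(DEFAULTS) - set(self.params)
        if missing:
            raise ValueError(f"unresolved configuration key(s): {sorted(missing)}")
        # constructing the parameter objects enforces every range invariant
        scenario_objects(self)


def scenario_objects(
    scenario: "Scenario",
) -> tuple[EnvironmentParams, CognitiveParams, PayoffParams]:
    """Build the typed parameter objects for a scenario (validates ranges)."""
    q = scenario.params

    def _fail(key, err):
        raise ValueError(f"invalid value for {key!r}: {err}") from err

    try:
        intensity = IntensityModel(
            kind=str(q["intensity_kind"]),
            mean=float(q["intensity_mean"]),
            sd=float(q["intensity_sd"]),
        )
    except ValueError as err:
        _fail("intensity_*", err)
    t_bar = float(q["t_bar"])
    if t_bar <= 0 or t_bar > 1.0 / float(q["lambda_d"]):
        raise ValueError(
            f"invalid value for 't_bar': must lie in (0, 1/lambda_d], got {t_bar}"
        )
    try:
        env = EnvironmentParams(
            lambda_e=1.0 / t_bar - float(q["lambda_d"]),
            lambda_d=float(q["lambda_d"]),
            p=float(q["p"]),
            psi=float(q["psi"]),
            assort_w=float(q["assort_w"]),
            intensity=intensity,
        )
    except ValueError as err:
        _fail("p/psi/assort_w/lambda_d", err)
    try:
        cog = CognitiveParams(
            gamma=float(q["gamma"]),
            gamma_s=float(q["gamma_s"]),
            gamma_a=float(q["gamma_a"]),
            rho_l=float(q["rho_l"]),
            rho_a=float(q["rho_a"]),
            lambda_l=float(q["lambda_l"]),
            u_B=float(q["u_B"]),
            u_D=float(q["u_D"]),
            activation_kind=str(q["activation_kind"]),
        )
    except ValueError as err:
        _fail("cognitive parameter", err)
    pay = PayoffParams(
        b=float(q["b"]),
        d_minus=float(q["d_minus"]),
        d_plus=float(q["d_plus"]),
        c_minus=float(q["c_minus"]),
        c_plus=float(q["c_plus"]),
    )
    return env, cog, pay


def _resolved(overrides: dict, name: str, out_dir: str | None) -> Scenario:
    bad = set(overrides) - set(DEFAULTS) - {"name", "target", "out_dir"}
    if bad:
        raise ValueError(f"unknown configuration key(s): {sorted(bad)}")
    params = copy.deepcopy(DEFAULTS)
    params.update({k: v for k, v in overrides.items() if k in DEFAULTS})
    target = str(overrides.get("target", "sweep"))
    return Scenario(name=name, target=target, params=params, out_dir=out_dir)


def load_config(path: str | Path | None = None, fixture: str | None = None) -> Scenario:
    """Scenario from a named fixture and/or a YAML override file.

    Precedence: package defaults < fixture overrides < file overrides.  An
    empty file yields the all-defaults sweep scenario.
    """
    overrides: dict[str, object] = {}
    name = fixture or "custom"
    if fixture is not None:
        if fixture not in FIXTURES:
            raise ValueError(f"unknown fixture {fixture!r}; available: {sorted(FIXTURES)}")
        overrides.update(FIXTURES[fixture])
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        name = str(raw.pop("name", name))
        overrides.update(raw)
    out_dir = overrides.pop("out_dir", None)
    return _resolved(overrides, name, out_dir)


def write_config(scenario: Scenario, path: str | Path) -> None:
    """Serialize a scenario so that load_config round-trips it."""
    doc = {"name": scenario.name, "target": scenario.target, **scenario.params}
    if scenario.out_dir is not None:
        doc["out_dir"] = scenario.out_dir
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _write_csv(df, path: Path, scenario: Scenario, seed: int | None) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# mindread {__version__}\n")
        fh.write(f"# scenario: {scenario.name} target: {scenario.target}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for k in sorted(scenario.params):
            fh.write(f"# {k}: {scenario.params[k]}\n")
        df.to_csv(fh, index=False)


def run_scenario(
    scenario: Scenario,
    out_dir: str | Path | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Execute a scenario and write its CSV outputs; returns the file paths.

    Analytic targets are deterministic; the agent-based target consumes the
    seed (recorded in every output header).
    """
    out = Path(out_dir or scenario.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    env, cog, pay = scenario_objects(scenario)
    q = scenario.params
    files: dict[str, Path] = {}

    if scenario.target == "sweep":
        grid = SweepGrid(
            t_bar=np.linspace(float(q["t_bar_min"]), float(q["t_bar_max"]), int(q["n_t_bar"])),
            p=np.linspace(float(q["p_min"]), float(q["p_max"]), int(q["n_p"])),
        )
        swept = phase_diagram(grid, env, cog, pay)
        path = out / f"{scenario.name}_sweep.csv"
        _write_csv(swept.table, path, scenario, None)
        files["sweep"] = path
    elif scenario.target == "invade":
        traits = {t.strip() for t in str(q["traits"]).split(",")}
        points = singular_numeric(env, cog, pay, which=traits)
        import pandas as pd

        sp, prof = equilibrium_profile(env, cog, pay, check_bound=False)
        rows = [
            {
                "u_D_star": p_.u_D,
                "u_B_star": p_.u_B if p_.u_B is not None else cog.u_B,
                "is_ESS": p_.is_ESS,
                "is_CS": p_.is_CS,
                "branch": p_.branch,
                "P_B": prof.P_B,
                "P_D": prof.P_D,
                "P_C": prof.P_C,
            }
            for p_ in points
        ]
        path = out / f"{scenario.name}_singular.csv"
        _write_csv(pd.DataFrame(rows), path, scenario, None)
        files["singular"] = path
        n_field = int(q["field_n"])
        if n_field > 0:
            field = gradient_field(
                np.linspace(0.02, 1.2, n_field),
                np.linspace(0.08, 0.92, n_field),
                env,
                cog,
                pay,
            )
            fpath = out / f"{scenario.name}_gradient_field.csv"
            _write_csv(field, fpath, scenario, None)
            files["gradient_field"] = fpath
    elif scenario.target == "kin":
        table = regime_map(
            np.linspace(float(q["r_min"]), float(q["r_max"]), int(q["n_r"])),
            np.linspace(float(q["c_ratio_min"]), float(q["c_ratio_max"]), int(q["n_c_ratio"])),
            env,
            cog,
            pay,
        )
        path = out / f"{scenario.name}_regimes.csv"
        _write_csv(table, path, scenario, None)
        files["regimes"] = path
    else:  # abm
        cfg = ABMConfig(
            n_agents=int(q["n_agents"]),
            generations=int(q["generations"]),
            steps_per_generation=int(q["steps_per_generation"]),
            dt=float(q["dt"]),
            seed=seed,
        )
        cells = [(float(q["t_bar"]), float(q["p"])), (float(q["t_bar_max"]), float(q["p"]))]
        report = validate_against_replicator(
            cells, env, cog, pay, cfg, n_replicates=int(q["n_replicates"])
        )
        path = out / f"{scenario.name}_abm_agreement.csv"
        _write_csv(report, path, scenario, seed)
        files["abm_agreement"] = path
    return files
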