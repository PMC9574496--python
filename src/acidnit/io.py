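"""Structured-text configuration for kinetics and scenarios.

Kinetics configs are YAML with one block per reaction — id, rate law,
constants with units, reversibility — validated against a pydantic schema
on load.  Values survive a load -> dump -> load cycle exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field

from .kinetics import ChemKineticsParams, GasTransferParams
from .synth import ScenarioConfig

__all__ = [
    "KineticsConfig",
    "load_kinetics_config",
    "dump_kinetics_config",
    "kinetics_config_from_params",
    "load_scenario_config",
    "dump_scenario_config",
]


class Constant(BaseModel):
    value: float
    units: str


class ReactionBlock(BaseModel):
    id: Literal["R2", "R3", "R4", "R56"]
    law: Literal["mass_action", "quasi_steady_n2o3"]
    reversible: bool = False
    constants: dict[str, Constant]
    nh3_branch_enabled: Optional[bool] = None


class GasTransferBlock(BaseModel):
    kLa_NO: Constant
    kLa_NO2: Constant
    aeration_off_factor: float = Field(ge=0, le=1)


class KineticsConfig(BaseModel):
    """Full reaction-network parameterization as stored on disk."""

    reactions: list[ReactionBlock]
    gas_transfer: GasTransferBlock

    def to_params(self) -> tuple[ChemKineticsParams, GasTransferParams]:
        by_id = {b.id: b for b in self.reactions}
        missing = {"R2", "R3", "R4", "R56"} - set(by_id)
        if missing:
            raise ValueError(f"kinetics config missing reaction blocks: {sorted(missing)}")

        def const(block: ReactionBlock, name: str) -> float:
            if name not in block.constants:
                raise ValueError(f"reaction {block.id} missing constant {name!r}")
            return block.constants[name].value

        r2, r3, r4, r56 = by_id["R2"], by_id["R3"], by_id["R4"], by_id["R56"]
        params = ChemKineticsParams(
            k2_fwd=const(r2, "k_fwd"),
            k2_rev=const(r2, "k_rev") if r2.reversible else 0.0,
            k3=const(r3, "k"),
            k4_fwd=const(r4, "k_fwd"),
            k4_rev=const(r4, "k_rev") if r4.reversible else 0.0,
            k_n2o3=const(r56, "k_n2o3"),
            K_nh3_branch=const(r56, "K_nh3_branch"),
            nh3_branch_enabled=(
                r56.nh3_branch_enabled if r56.nh3_branch_enabled is not None else True
            ),
            theta_2=const(r2, "theta") if "theta" in r2.constants else 1.0,
            theta_3=const(r3, "theta") if "theta" in r3.constants else 1.0,
            theta_4=const(r4, "theta") if "theta" in r4.constants else 1.0,
            theta_56=const(r56, "theta") if "theta" in r56.constants else 1.0,
        )
        gas = GasTransferParams(
            kLa_NO=self.gas_transfer.kLa_NO.value,
            kLa_NO2=self.gas_transfer.kLa_NO2.value,
            aeration_off_factor=self.gas_transfer.aeration_off_factor,
        )
        return params, gas


def kinetics_config_from_params(
    params: ChemKineticsParams, gas: GasTransferParams
) -> KineticsConfig:
    """Express in-memory parameters in the on-disk schema."""

    def c(value: float, units: str) -> Constant:
        return Constant(value=value, units=units)

    return KineticsConfig(
        reactions=[
            ReactionBlock(
                id="R2",
                law="mass_action",
                reversible=params.k2_rev > 0,
                constants={
                    "k_fwd": c(params.k2_fwd, "L mol-1 d-1"),
                    "k_rev": c(params.k2_rev, "L mol-1 d-1"),
                    "theta": c(params.theta_2, "-"),
                },
            ),
            ReactionBlock(
                id="R3",
                law="mass_action",
                reversible=False,
                constants={
                    "k": c(params.k3, "L2 mol-2 d-1"),
                    "theta": c(params.theta_3, "-"),
                },
            ),
            ReactionBlock(
                id="R4",
                law="mass_action",
                reversible=params.k4_rev > 0,
                constants={
                    "k_fwd": c(params.k4_fwd, "L mol-1 d-1"),
                    "k_rev": c(params.k4_rev, "L2 mol-2 d-1"),
                    "theta": c(params.theta_4, "-"),
                },
            ),
            ReactionBlock(
                id="R56",
                law="quasi_steady_n2o3",
                reversible=False,
                constants={
                    "k_n2o3": c(params.k_n2o3, "L mol-1 d-1"),
                    "K_nh3_branch": c(params.K_nh3_branch, "L mol-1"),
                    "theta": c(params.theta_56, "-"),
                },
                nh3_branch_enabled=params.nh3_branch_enabled,
            ),
        ],
        gas_transfer=GasTransferBlock(
            kLa_NO=c(gas.kLa_NO, "d-1"),
            kLa_NO2=c(gas.kLa_NO2, "d-1"),
            aeration_off_factor=gas.aeration_off_factor,
        ),
    )


def load_kinetics_config(path: str | Path) -> tuple[ChemKineticsParams, GasTransferParams]:
    """Load and validate a kinetics YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return KineticsConfig.model_validate(raw).to_params()


def dump_kinetics_config(
    params: ChemKineticsParams, gas: GasTransferParams, path: str | Path
) -> None:
    """Write a kinetics YAML file that loads back to identical parameters."""
    cfg = kinetics_config_from_params(params, gas)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ScenarioConfig.model_validate(raw)


def dump_scenario_config(config: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
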