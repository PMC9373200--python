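"""YAML/JSON run configuration: design + outcome model + monitoring plan.

Schema (top-level keys)::

    design:
      randomisations:        # required; one control arm per randomisation
        - id: A
          arms:
            - {id: A0, role: control, weight: 1}
            - {id: A1, role: research, weight: 1}
      targets: 3000          # single number, or mapping comparison-id -> n
      stratification_factors: {site: [1, 2]}      # optional
      accrual_rate: 100                           # patients per unit time
      adaptations:                                # optional, times in patients
        - {kind: add_intervention, target: A, new_arm: A2, time: 1500}
    outcome_model:           # optional (defaults: binary, p0 0.2, no effects)
      outcome_type: binary
      baseline: 0.2
      effects: {A1: 0.8}
      intermediate_baseline: 0.3
      intermediate_rho: 1.0
    monitoring:              # optional (no plan => single final analysis)
      triggers: [{type: calendar, time: 15.0}]
      efficacy: haybittle_peto
      futility_bounds: [0.0]
      alpha: 0.025
    simulation:              # optional run_trial keyword overrides
      block_multiples: [1, 2]
      eligibility_probs: {A1: 0.95}

Validation failures are reported all at once with explicit messages.
"""

from __future__ import annotations

import yaml

from .design import DesignError, TrialDesign, load_design
from .monitoring import MonitoringPlan
from .outcomes import OutcomeModel

__all__ = ["RunConfig", "load_config"]


class RunConfig:
    def __init__(self, design: TrialDesign, model: OutcomeModel, plan: MonitoringPlan | None, simulation: dict):
        self.design = design
        self.model = model
        self.plan = plan
        self.simulation = simulation


def load_config(path_or_dict) -> RunConfig:
    """Parse and validate a full run configuration."""
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    elif hasattr(path_or_dict, "read"):
        cfg = yaml.safe_load(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    errors: list[str] = []
    if "design" not in cfg:
        raise DesignError("config must contain a 'design' section")
    try:
        design = load_design(cfg["design"])
    except (DesignError, KeyError, TypeError, ValueError) as exc:
        errors.append(f"design: {exc}")
        design = None
    model = OutcomeModel()
    if "outcome_model" in cfg:
        om = dict(cfg["outcome_model"])
        if "interactions" in om:
            om["interactions"] = {
                frozenset(str(k).split("+")): v for k, v in om["interactions"].items()
            }
        try:
            model = OutcomeModel(**om)
        except (TypeError, ValueError) as exc:
            errors.append(f"outcome_model: {exc}")
    plan = None
    if "monitoring" in cfg:
        try:
            plan = MonitoringPlan(**cfg["monitoring"])
        except (TypeError, ValueError) as exc:
            errors.append(f"monitoring: {exc}")
    simulation = dict(cfg.get("simulation", {}))
    if "block_multiples" in simulation:
        simulation["block_multiples"] = tuple(simulation["block_multiples"])
    if errors:
        raise DesignError("invalid configuration: " + "; ".join(errors))
    return RunConfig(design, model, plan, simulation)
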