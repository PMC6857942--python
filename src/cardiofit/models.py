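"""Cell-model definitions.

Provides the ten Tusscher et al. (2004) human ventricular epicardial model
(the *base model* being tuned), a passive linear membrane whose true
resistance is known analytically (the testing oracle for the
membrane-resistance protocol), static voltage-dependent membranes for
constructing resistance singularities with known roots, and the reference
AP configurations (baseline, shortened/prolonged APD, hyper-/hypokalemia)
used as synthetic "experimental" fitting targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from . import _tnnp_kernel as _kernel
from .exceptions import ConfigurationError

#: the 16 tunable maximal conductances / rates, in canonical order
PARAM_NAMES: tuple[str, ...] = (
    "G_Na", "G_CaL", "G_bNa", "G_bCa", "G_Kr", "G_to", "G_K1", "G_Ks",
    "G_pK", "P_NaK", "k_NaCa", "G_pCa", "V_maxup", "c_rel", "a_rel", "V_leak",
)

#: default box bounds on the dimensionless scale factors.  Wide enough to
#: cover the physiological perturbations explored by the reference
#: configurations while keeping the model excitable.
DEFAULT_LB = 0.1
DEFAULT_UB = 3.0

#: capacitance all resistance values are normalized to (pF)
NORMALIZATION_CAPACITANCE_PF = 180.0


@dataclass
class ModelParameters:
    """Dimensionless scale factors on the 16 tunable model constants.

    ``scale[name]`` multiplies the published nominal value of ``name``;
    all-ones therefore reproduces the nominal model.
    """

    scale: dict[str, float]
    lb: dict[str, float] = field(default_factory=dict)
    ub: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.scale) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown scale factor(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(self.scale)
        if missing:
            raise ConfigurationError(f"missing scale factor(s): {sorted(missing)}")
        for name in PARAM_NAMES:
            self.lb.setdefault(name, DEFAULT_LB)
            self.ub.setdefault(name, DEFAULT_UB)
            v = self.scale[name]
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"scale factor {name} must be strictly positive, got {v}")
            if not (self.lb[name] <= v <= self.ub[name]):
                raise ValueError(
                    f"scale factor {name}={v} outside bounds "
                    f"[{self.lb[name]}, {self.ub[name]}]")

    @classmethod
    def nominal(cls) -> "ModelParameters":
        return cls(scale={name: 1.0 for name in PARAM_NAMES})

    @classmethod
    def from_vector(cls, x: np.ndarray, lb: float = DEFAULT_LB,
                    ub: float = DEFAULT_UB) -> "ModelParameters":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise ConfigurationError(
                f"parameter vector must have length {len(PARAM_NAMES)}")
        return cls(scale=dict(zip(PARAM_NAMES, x.tolist())),
                   lb={n: lb for n in PARAM_NAMES},
                   ub={n: ub for n in PARAM_NAMES})

    def as_vector(self) -> np.ndarray:
        return np.array([self.scale[n] for n in PARAM_NAMES])


@dataclass
class CellModel:
    """Contract between a membrane model and the pacing/clamp engine.

    ``rhs(t, y)`` is the free-running state derivative (no stimulus) and
    ``total_ionic_current(y)`` the membrane current I_m in pA/pF; the two
    are consistent: dVm/dt = -(I_ion + I_stim).
    """

    name: str
    state_dimension: int
    vm_index: int
    rhs: Callable[[float, np.ndarray], np.ndarray]
    total_ionic_current: Callable[[np.ndarray], float]
    capacitance_pF: float
    conditions: dict
    initial_state: np.ndarray
    #: engine dispatch tag: "tnnp" uses the compiled kernel, anything else
    #: the generic fixed-step python integrator
    kind: str = "generic"
    #: premultiplied kernel parameter vector (tnnp only)
    p: np.ndarray | None = None
    #: the scale factors this model was built from, if any
    params: ModelParameters | None = None

    def __post_init__(self):
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance_pF must be positive")


def build_tnnp_model(params: ModelParameters | None = None,
                     conditions: Mapping[str, float] | None = None) -> CellModel:
    """Build the TNNP 2004 epicardial model with scaled conductances.

    ``conditions`` may override extracellular potassium via ``ko_mM``
    (nominal 5.4 mM).  All other equation constants are the published
    nominal epicardial values.
    """
    params = params or ModelParameters.nominal()
    cond = {"ko_mM": _kernel.KO_NOMINAL}
    if conditions:
        unknown = set(conditions) - {"ko_mM"}
        if unknown:
            raise ConfigurationError(f"unknown condition(s): {sorted(unknown)}")
        cond.update(conditions)
    if cond["ko_mM"] <= 0:
        raise ValueError("extracellular [K+] must be positive")

    p = _kernel.make_param_vector(params.as_vector(), cond["ko_mM"])

    def rhs(t, y, _p=p):
        return _kernel.rhs(t, np.asarray(y, dtype=float), _p, 0.0)

    def im(y, _p=p):
        return _kernel.total_ionic_current(np.asarray(y, dtype=float), _p)

    return CellModel(
        name="tnnp_epi",
        state_dimension=_kernel.N_STATE,
        vm_index=_kernel.V_INDEX,
        rhs=rhs,
        total_ionic_current=im,
        capacitance_pF=_kernel.CAPACITANCE_PF,
        conditions=cond,
        initial_state=_kernel.INITIAL_STATE.copy(),
        kind="tnnp",
        p=p,
        params=params,
    )


def build_passive_membrane(resistance_GOhm_at_180pF: float,
                           reversal_mV: float = -85.0,
                           capacitance_pF: float = 180.0) -> CellModel:
    """One-state linear membrane with a known normalized resistance.

    The current density is I_m = (Vm - E) / (R180 * 180) pA/pF, so the
    measured resistance normalized to 180 pF equals
    ``resistance_GOhm_at_180pF`` at every voltage regardless of the cell's
    own capacitance.  The unstimulated trajectory is the RC relaxation
    Vm(t) = E + (V0 - E) exp(-t / (R_abs * C)) with R_abs = R180 * 180 / C.
    """
    if resistance_GOhm_at_180pF <= 0:
        raise ValueError("resistance must be positive")
    if capacitance_pF <= 0:
        raise ValueError("capacitance must be positive")
    denom = resistance_GOhm_at_180pF * NORMALIZATION_CAPACITANCE_PF  # GOhm*pF = ms

    def im(y):
        return (y[0] - reversal_mV) / denom

    def rhs(t, y):
        return np.array([-(y[0] - reversal_mV) / denom])

    return CellModel(
        name="passive",
        state_dimension=1,
        vm_index=0,
        rhs=rhs,
        total_ionic_current=im,
        capacitance_pF=capacitance_pF,
        conditions={"reversal_mV": reversal_mV,
                    "resistance_GOhm_at_180pF": resistance_GOhm_at_180pF},
        initial_state=np.array([reversal_mV]),
        kind="generic",
    )


def build_static_membrane(current_of_v: Callable[[float], float],
                          name: str = "static",
                          initial_mV: float = -85.0,
                          capacitance_pF: float = 180.0) -> CellModel:
    """State-free membrane whose current depends on voltage only.

    Useful as an analytic oracle: the clamp protocol's measured resistance
    is exactly 20 mV / (I(v+10) - I(v-10)) normalized, with no gating
    dynamics involved.
    """

    def im(y):
        return current_of_v(y[0])

    def rhs(t, y):
        return np.array([-current_of_v(y[0])])

    return CellModel(
        name=name,
        state_dimension=1,
        vm_index=0,
        rhs=rhs,
        total_ionic_current=im,
        capacitance_pF=capacitance_pF,
        conditions={},
        initial_state=np.array([initial_mV]),
        kind="generic",
    )


@dataclass
class ConfigurationSpec:
    """Declarative description of a reference AP configuration."""

    name: str
    parameter_overrides: dict[str, float] = field(default_factory=dict)
    ko_mM: float = _kernel.KO_NOMINAL

    KNOWN = ("baseline", "shortened_apd", "prolonged_apd",
             "hyperkalemia", "hypokalemia", "custom")

    def __post_init__(self):
        if self.name not in self.KNOWN:
            raise ConfigurationError(f"unknown configuration name: {self.name!r}")


#: fixed, documented scale-factor draw defining the baseline reference
#: configuration.  Deliberately distinct from all-ones so that fitting the
#: nominal base model to it is non-trivial while the ground truth is known.
BASELINE_REFERENCE_SCALES: dict[str, float] = {
    "G_Na": 1.15, "G_CaL": 0.85, "G_bNa": 1.20, "G_bCa": 0.90,
    "G_Kr": 1.30, "G_to": 0.80, "G_K1": 1.10, "G_Ks": 0.70,
    "G_pK": 1.25, "P_NaK": 0.95, "k_NaCa": 1.10, "G_pCa": 0.90,
    "V_maxup": 1.05, "c_rel": 0.95, "a_rel": 1.10, "V_leak": 0.85,
}

#: delayed-rectifier availability changes emulating shortened / prolonged APD
SHORTENED_APD_SCALES = {"G_Kr": 2.5, "G_Ks": 2.5}
PROLONGED_APD_SCALES = {"G_Kr": 0.4, "G_Ks": 0.4}

KO_HYPERKALEMIA_MM = 6.5
KO_HYPOKALEMIA_MM = 3.0


def configuration_spec(name: str) -> ConfigurationSpec:
    """Canonical :class:`ConfigurationSpec` for each named configuration."""
    if name == "baseline":
        return ConfigurationSpec("baseline", dict(BASELINE_REFERENCE_SCALES))
    if name == "shortened_apd":
        return ConfigurationSpec("shortened_apd", dict(SHORTENED_APD_SCALES))
    if name == "prolonged_apd":
        return ConfigurationSpec("prolonged_apd", dict(PROLONGED_APD_SCALES))
    if name == "hyperkalemia":
        return ConfigurationSpec("hyperkalemia", {}, ko_mM=KO_HYPERKALEMIA_MM)
    if name == "hypokalemia":
        return ConfigurationSpec("hypokalemia", {}, ko_mM=KO_HYPOKALEMIA_MM)
    raise ConfigurationError(f"unknown configuration name: {name!r}")


def make_reference_configuration(spec: ConfigurationSpec | str) -> CellModel:
    """Build the perturbed-TNNP reference model for a configuration.

    The returned model records its ground-truth scale factors in
    ``model.params`` so that parameter-recovery experiments can compare the
    fitted vector against the truth.
    """
    if isinstance(spec, str):
        spec = configuration_spec(spec)
    scales = {name: 1.0 for name in PARAM_NAMES}
    scales.update(spec.parameter_overrides)
    params = ModelParameters(scale=scales)
    model = build_tnnp_model(params, {"ko_mM": spec.ko_mM})
    model.name = f"tnnp_reference_{spec.name}"
    return model
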