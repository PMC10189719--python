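"""Binocular contrast-normalization observer model.

The model has four free parameters. The amblyopic eye's (AE) input is
linearly attenuated by ``k_ae`` (the fellow eye, FE, is unattenuated,
``k_fe = 1``); each eye's attenuated signal is then divisively
normalized by the other eye's signal plus a saturation constant, and
the perceived contrast is the sum of the two normalized outputs:

.. math::

    A_{AE} = k_{AE} C_{AE}, \\qquad A_{FE} = C_{FE}

    \\hat C_{AE} = \\frac{A_{AE}}{\\mu_{AE} C_{FE} + \\sigma}, \\qquad
    \\hat C_{FE} = \\frac{C_{FE}}{\\mu_{FE} A_{AE} + \\sigma}

    \\hat C = \\hat C_{AE} + \\hat C_{FE}

``mu_ae`` measures how strongly the fellow eye suppresses the amblyopic
eye; ``mu_fe`` the reverse. With ``mu_ae = mu_fe = 0`` and ``sigma = 1``
the model reduces to the purely linear monocular-attenuation form used
when only one eye is stimulated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ContractViolationError
from .stimulus import TrialTimecourse

__all__ = [
    "ObserverParams",
    "ModelPrediction",
    "predict_perceived",
    "predict_monoptic",
    "predict_trial",
    "load_params",
    "save_params",
    "PRESETS",
]


@dataclass
class ObserverParams:
    """Parameters of the normalization observer.

    ``k_ae`` in (0, 1] is the amblyopic eye's attenuation weight (the
    fellow eye's weight is fixed at 1); ``mu_ae``, ``mu_fe`` >= 0 are
    interocular normalization weights (fellow-on-amblyopic and
    amblyopic-on-fellow, respectively); ``sigma`` > 0 is the saturation
    constant. ``ae_eye`` designates which physical eye is amblyopic.
    """

    k_ae: float = 1.0
    mu_ae: float = 0.0
    mu_fe: float = 0.0
    sigma: float = 1.0
    ae_eye: str = "left"

    #: the fellow eye's attenuation weight is 1 by construction
    k_fe: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.k_ae <= 1.0:
            raise ValueError(f"k_ae must be in (0, 1], got {self.k_ae}")
        if self.mu_ae < 0 or self.mu_fe < 0:
            raise ValueError("mu_ae and mu_fe must be >= 0")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.ae_eye not in ("left", "right"):
            raise ValueError(f"ae_eye must be 'left' or 'right', got {self.ae_eye!r}")
        if self.k_fe != 1.0:
            raise ValueError("k_fe is fixed at 1")

    @property
    def fe_eye(self) -> str:
        return "right" if self.ae_eye == "left" else "left"


#: Group-mean parameter presets for three canonical observer groups:
#: controls, amblyopia, and non-amblyopic strabismus with equal acuity.
PRESETS: dict[str, ObserverParams] = {
    "control": ObserverParams(k_ae=0.91, mu_ae=0.80, mu_fe=0.90, sigma=1.10),
    "amblyopia": ObserverParams(k_ae=0.42, mu_ae=3.04, mu_fe=0.20, sigma=1.02),
    "strabismus": ObserverParams(k_ae=0.65, mu_ae=1.86, mu_fe=0.24, sigma=1.23),
}


@dataclass
class ModelPrediction:
    """Per-sample components of the model's perceived-contrast prediction."""

    a_ae: np.ndarray
    a_fe: np.ndarray
    c_hat_ae: np.ndarray
    c_hat_fe: np.ndarray
    c_hat: np.ndarray


def _validate_contrasts(*series: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(s, dtype=float) for s in series]
    n = {a.shape for a in arrs}
    if len(n) != 1:
        raise ValueError(f"contrast series have mismatched shapes: {sorted(n)}")
    for a in arrs:
        if a.size and (np.nanmin(a) < -1e-9 or np.nanmax(a) > 1.0 + 1e-9):
            raise ValueError("contrast values must lie in [0, 1]")
    return arrs


def predict_perceived(
    params: ObserverParams, c_ae: np.ndarray, c_fe: np.ndarray
) -> ModelPrediction:
    """Predicted perceived contrast for amblyopic/fellow-eye inputs.

    Both series must be the same length with values in [0, 1].
    """
    c_ae, c_fe = _validate_contrasts(c_ae, c_fe)
    a_ae = params.k_ae * c_ae
    a_fe = c_fe.copy()
    c_hat_ae = a_ae / (params.mu_ae * c_fe + params.sigma)
    c_hat_fe = c_fe / (params.mu_fe * a_ae + params.sigma)
    return ModelPrediction(
        a_ae=a_ae,
        a_fe=a_fe,
        c_hat_ae=c_hat_ae,
        c_hat_fe=c_hat_fe,
        c_hat=c_hat_ae + c_hat_fe,
    )


def predict_monoptic(
    k_left: float, k_right: float, c_left: np.ndarray, c_right: np.ndarray
) -> np.ndarray:
    """Linear monocular-attenuation prediction for monoptic stimulation.

    ``(k_R C_R + k_L C_L) / max(k_R, k_L)`` — valid only where at most
    one eye is stimulated per sample. The max-normalization fixes the
    stronger eye's effective weight at 1.
    """
    if not (k_left > 0 and k_right > 0):
        raise ValueError("attenuation weights must be positive")
    c_left, c_right = _validate_contrasts(c_left, c_right)
    if np.any((c_left > 0) & (c_right > 0)):
        raise ContractViolationError(
            "monoptic prediction requires at least one zero contrast per sample"
        )
    return (k_right * c_right + k_left * c_left) / max(k_right, k_left)


def predict_trial(params: ObserverParams, trial: TrialTimecourse) -> np.ndarray:
    """Total predicted perceived contrast over a trial's time grid,
    mapping the trial's physical eyes onto the AE/FE designation."""
    c_ae = trial.contrast(params.ae_eye)
    c_fe = trial.contrast(params.fe_eye)
    return predict_perceived(params, c_ae, c_fe).c_hat


def save_params(params: ObserverParams, path: str | Path) -> None:
    """Write a parameter set to a YAML key-value file."""
    d = asdict(params)
    d.pop("k_fe")
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_params(path: str | Path) -> ObserverParams:
    """Read a parameter set from a YAML key-value file."""
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    return ObserverParams(**d)
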