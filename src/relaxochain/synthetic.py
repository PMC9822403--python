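"""Synthetic relaxometry data: CPMG trains, oil panels, IR-CPMG mixtures.

Emulates a 23 MHz benchtop acquisition (TE 0.3 ms, ~1000 echoes, 16
scans, TR 10 s) with additive Gaussian noise on the echo magnitudes.
Everything is deterministic under a fixed seed, so test inputs are
regenerated on the fly rather than stored.

Per-oil truth values come from the bundled 17-oil reference panel.  For
single-train generation by oil name the tabulated T2 column is used
verbatim; for the full calibration panel the truth T2 is derived from
the tabulated rate column (T2 = 1000/R2), which carries ~6 significant
digits against the T2 column's 2-4, so that a noiseless
generate → fit → calibrate round trip reproduces the reference
regression to the precision of the printed coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import OilRecord
from .cpmg import AcquisitionMeta, EchoTrain
from .oiltable import load_table1
from .t1t2 import IRCPMGSeries, simulate_ir_cpmg

__all__ = ["SyntheticSpec", "make_cpmg", "make_oil_panel", "make_ir_cpmg_mixture"]

DEFAULT_M0 = 100.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic acquisition.

    Exactly one of ``oil_name`` / ``t2_ms`` / ``components`` defines the
    decay: an oil from the bundled panel, an explicit mono-exponential
    T2, or a list of (T1 ms, T2 ms, weight) mixture components for
    IR-CPMG generation.  ``noise_sigma_rel`` is the Gaussian noise
    standard deviation as a fraction of the initial amplitude; 0.005
    reflects the high SNR of 16 averaged scans on neat oil.
    """

    oil_name: str | None = None
    t2_ms: float | None = None
    components: tuple[tuple[float, float, float], ...] = ()
    noise_sigma_rel: float = 0.005
    seed: int | None = None
    m0: float = DEFAULT_M0
    echo_time_ms: float = 0.3
    n_echoes: int = 1000
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self) -> None:
        if self.noise_sigma_rel < 0:
            raise ValueError("noise_sigma_rel must be nonnegative")


def _lookup_t2(oil_name: str) -> float:
    records = load_table1()
    for r in records:
        if r.name.lower() == oil_name.lower():
            return r.t2_ms
    names = ", ".join(r.name for r in records)
    raise KeyError(f"unknown oil {oil_name!r}; available oils: {names}")


def make_cpmg(spec: SyntheticSpec) -> EchoTrain:
    """Generate one noisy mono-exponential CPMG train from a spec.

    Amplitudes are M0 * exp(-k*TE/T2) + N(0, sigma^2) with
    sigma = noise_sigma_rel * M0, for k = 1..n_echoes.
    """
    if spec.t2_ms is not None:
        t2 = spec.t2_ms
    elif spec.oil_name is not None:
        t2 = _lookup_t2(spec.oil_name)
    else:
        raise ValueError("spec must define either t2_ms or oil_name")
    if t2 <= 0:
        raise ValueError("t2_ms must be positive")

    times = spec.echo_time_ms * np.arange(1, spec.n_echoes + 1)
    amps = spec.m0 * np.exp(-times / t2)
    if spec.noise_sigma_rel > 0:
        rng = np.random.default_rng(spec.seed)
        amps = amps + rng.normal(0.0, spec.noise_sigma_rel * spec.m0, amps.shape)
    return EchoTrain(spec.echo_time_ms, amps, spec.meta)


def make_oil_panel(
    noise_sigma_rel: float = 0.005,
    seed: int | None = None,
    echo_time_ms: float = 0.3,
    n_echoes: int = 1000,
) -> list[tuple[OilRecord, EchoTrain]]:
    """One synthetic CPMG train per liquid oil of the bundled reference panel.

    The per-oil truth T2 is 1000/R2 from the tabulated rate column (see
    module docstring).  Seeds for the individual trains are derived from
    ``seed`` so the panel as a whole is reproducible.
    """
    records = [r for r in load_table1() if r.is_liquid]
    master = np.random.default_rng(seed)
    panel = []
    for rec in records:
        spec = SyntheticSpec(
            t2_ms=1000.0 / rec.r2_per_s,
            noise_sigma_rel=noise_sigma_rel,
            seed=int(master.integers(0, 2**31 - 1)),
            echo_time_ms=echo_time_ms,
            n_echoes=n_echoes,
        )
        panel.append((rec, make_cpmg(spec)))
    return panel


def make_ir_cpmg_mixture(spec: SyntheticSpec) -> IRCPMGSeries:
    """Generate an IR-CPMG series for the mixture components in ``spec``.

    Noise sigma is ``noise_sigma_rel`` times the total component weight
    (the t -> 0, full-recovery amplitude of the mixture).
    """
    if not spec.components:
        raise ValueError("spec.components must list at least one (T1, T2, weight)")
    total_weight = sum(w for _, _, w in spec.components)
    return simulate_ir_cpmg(
        list(spec.components),
        echo_time_ms=spec.echo_time_ms,
        n_echoes=spec.n_echoes,
        noise_sigma=spec.noise_sigma_rel * total_weight,
        seed=spec.seed,
        meta=spec.meta,
    )
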