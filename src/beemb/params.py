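"""Model parameters for the mushroom-body circuit models.

All parameters are in arbitrary units. The defaults describe a three-layer
linear-threshold network: 144 input neurons (IN) project sparsely onto 5000
Kenyon cells (KC), which drive 8 extrinsic output neurons (EN, split into GO
and NOGO subpopulations) and 6 inhibitory protocerebral-tract (PCT) neurons.
Repeated stimuli within a trial are attenuated by a multiplicative sensory
accommodation factor, which is what lets the high-threshold PCT neurons act
as novelty detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from math import comb


@dataclass(frozen=True)
class ModelParams:
    """All constants of the full and reduced circuit models.

    Counts and thresholds follow the published parameter table; the few
    quantities the circuit description leaves open (`kc_gain`,
    ``pct_drive_target``, the reduced-model constants ``theta``/``x_min``/
    ``x_max``/``w_max``/``w_exc``) are calibration choices documented in
    ``docs/methods.md``.
    """

    # -- full-model architecture -------------------------------------------
    n_in: int = 144
    n_kc: int = 5000
    n_en: int = 8
    n_pct: int = 6
    p_in_kc: float = 0.02
    group_size: int = 8              # IN neurons per stimulus group

    # -- thresholds and gains ----------------------------------------------
    b: float = 1.2                   # KC activation threshold
    b_s_low: float = 120.0           # PCT threshold, unit l = 0
    b_s_high: float = 150.0          # PCT threshold, units l > 0
    accommodation_factor: float = 0.7
    pct_en_scale: float = 0.5        # scale of PCT inhibition at the EN
    pct_saturates: bool = True       # per-unit PCT output cut-off
    pct_delay: int = 10              # iterations of KC->PCT->KC loop delay
    kc_gain: float | None = None           # KC output gain; None => calibrated
    pct_drive_target: float | None = None  # novel-stimulus KC drive target

    # -- learning ----------------------------------------------------------
    lambda_e: float = 0.06           # excitatory (KC->EN) learning rate
    lambda_i: float = 0.03           # inhibitory (PCT->EN) learning rate
    r_b: float = 2.0 / 3.0           # reward baseline
    w_init: float = 0.5              # initial plastic weight (both matrices)

    # -- decision readout --------------------------------------------------
    decision_floor: float = 0.1      # minimum total EN activity to decide
    nogo_bias_step: float = 10.0     # bias increment per NOGO decision
    max_iter_per_position: int = 100
    max_nogo_per_trial: int = 1000

    # -- reduced model -----------------------------------------------------
    c: float = 80.0                  # sigmoid gain
    d0: float = 1.0                  # per-iteration bias constant
    theta: float = 0.85              # novelty-node threshold
    x_min: float = 0.0
    x_max: float = 10.0
    w_max: float = 1.0               # inhibitory weight ceiling
    w_exc: float = 1.0               # fixed excitatory weight

    # -- stimulus encoding -------------------------------------------------
    jitter_half_width: float = 0.05  # active IN value is 1 - U[-jhw, jhw]

    def __post_init__(self) -> None:
        for name in ("n_in", "n_kc", "n_en", "n_pct", "group_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.p_in_kc < 1.0:
            raise ValueError("p_in_kc must lie in [0, 1)")
        if not 0.0 < self.r_b < 1.0:
            raise ValueError("r_b must lie in (0, 1)")
        if not 0.0 < self.accommodation_factor < 1.0:
            raise ValueError("accommodation_factor must lie in (0, 1)")
        if abs(self.lambda_e - 2.0 * self.lambda_i) > 1e-12:
            raise ValueError("lambda_e must equal 2 * lambda_i (2:1 ratio)")
        if self.n_en % 2 != 0:
            raise ValueError("n_en must split evenly into GO and NOGO")

    # -- derived quantities ------------------------------------------------

    @property
    def n_go(self) -> int:
        return self.n_en // 2

    def pct_thresholds(self):
        """Per-unit PCT thresholds: one low-threshold unit, the rest high."""
        import numpy as np

        t = np.full(self.n_pct, self.b_s_high)
        t[0] = self.b_s_low
        return t

    def expected_raw_kc_output(self) -> float:
        """Expected summed raw (gain 1) KC output for one novel stimulus.

        A KC connected to k of the ``group_size`` active inputs receives mean
        drive k (active values average 1), so contributes max(0, k - b). With
        b = 1.2 and jitter <= 5% the threshold never straddles an integer
        connection count (1.05 < b < 1.9), so the binomial expectation below
        is exact, not an approximation.
        """
        g, p = self.group_size, self.p_in_kc
        total = 0.0
        for k in range(1, g + 1):
            mean_drive = float(k)
            if mean_drive - self.b <= 0:
                continue
            pk = comb(g, k) * p**k * (1.0 - p) ** (g - k)
            total += pk * (mean_drive - self.b)
        return self.n_kc * total

    def pct_operable_window(self) -> tuple[float, float]:
        """Summed-KC-output interval in which every PCT unit responds to a
        novel stimulus (T > b_s_high) while none responds to an
        accommodated, repeated one (accommodation_factor * T < b_s_low) —
        the tuning that makes the whole PCT population a novelty detector.
        """
        return self.b_s_high, self.b_s_low / self.accommodation_factor

    def calibrated(self) -> "ModelParams":
        """Return a copy with ``kc_gain`` set so that the expected summed KC
        output to a novel stimulus equals ``pct_drive_target``.

        The default target sits a quarter of the way into the operable
        window. Random connectivity spreads per-stimulus totals around the
        target, and the two failure modes are asymmetric: a stimulus below
        the window merely loses its high-threshold novelty response (the
        low-threshold unit still signals novelty), while a stimulus above
        it leaks a PCT response to the accommodated repetition, actively
        mislabelling a matching arm as novel. The target therefore favours
        the quiet-when-repeated side of the window.
        """
        if self.kc_gain is not None:
            return self
        lo, hi = self.pct_operable_window()
        if lo >= hi:
            raise ValueError("PCT thresholds leave no operable window")
        target = self.pct_drive_target
        if target is None:
            target = lo + 0.25 * (hi - lo)
        raw = self.expected_raw_kc_output()
        if raw <= 0:
            raise ValueError("no KC is ever supra-threshold; cannot calibrate")
        return replace(self, kc_gain=target / raw)

    @property
    def gain(self) -> float:
        if self.kc_gain is None:
            raise ValueError("kc_gain not set; call .calibrated() first")
        return self.kc_gain

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)
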