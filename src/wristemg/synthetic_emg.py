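"""Seeded synthetic surface-EMG sessions with a known wrist-position effect.

The generator emulates the structure of a one-session recording protocol:
13 surface-EMG channels (9 forearm/"extrinsic", 4 hand/"intrinsic") sampled
at 1 kHz together with a 3-DOF wrist-angle trace, while the subject holds
one of four hand-motion classes (rest, open, chuck grasp, key grasp) for
3 s, six times, in each of 13 wrist positions (neutral plus end-range and
mid-range of flexion, extension, adduction, abduction, pronation and
supination).

The EMG model is the standard surface-EMG interference model: band-limited
(30-350 Hz) Gaussian noise whose per-channel standard deviation is an
amplitude ``gain(class, channel, wrist angles)``. The gain law is affine-
quadratic in the three wrist angles, so per-channel signal statistics vary
smoothly — but not linearly — with wrist position, which is exactly the
structure the downstream feature-ratio regression is supposed to learn.
``true_ratio`` exposes the analytic ground truth for parameter-recovery
tests: amplitude-proportional features (MAV, WL) scale with the gain ratio
and their variances with its square.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASSES = ("rest", "open", "chuck", "key")
#: degrees of freedom, in goniometer-trace order
DOF_NAMES = ("flexion_deg", "deviation_deg", "rotation_deg")

_PARAM_SEED = 733129  # fixed seed for the default modulation parameters


@dataclass(frozen=True)
class WristPosition:
    """Wrist posture in the three degrees of freedom, in degrees.

    Sign conventions: flexion positive / extension negative; adduction
    positive / abduction negative; pronation positive / supination negative.
    Neutral is (0, 0, 0).
    """

    flexion_deg: float = 0.0
    deviation_deg: float = 0.0
    rotation_deg: float = 0.0

    def __post_init__(self):
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("wrist angles must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.flexion_deg, self.deviation_deg, self.rotation_deg], float
        )


@dataclass(frozen=True)
class PositionGrid:
    """The 13 target wrist positions: neutral + end/mid range per direction."""

    end_range_deg: tuple[float, float, float] = (60.0, 20.0, 80.0)
    positions: tuple[WristPosition, ...] = ()

    def __post_init__(self):
        if not self.positions:
            object.__setattr__(self, "positions", self._build())
        if len(self.positions) != 13:
            raise ValueError("a position grid has exactly 13 entries")
        if self.positions[0].as_array().any():
            raise ValueError("entry 0 must be the neutral position")

    def _build(self) -> tuple[WristPosition, ...]:
        pos = [WristPosition()]
        for dof in range(3):
            end = self.end_range_deg[dof]
            for sign in (+1.0, -1.0):
                for mag in (end, end / 2.0):  # end-range then mid-range
                    a = [0.0, 0.0, 0.0]
                    a[dof] = sign * mag
                    pos.append(WristPosition(*a))
        return tuple(pos)

    def angles(self) -> np.ndarray:
        """(13, 3) array of target angles in degrees."""
        return np.stack([p.as_array() for p in self.positions])


@dataclass(frozen=True)
class ModulationParams:
    """Amplitude law of the generator.

    Per (class, channel) the EMG amplitude at wrist angles theta (degrees) is

        A = base_gain * (1 + sensitivity . theta + curvature . theta^2)
            + noise_floor

    with elementwise theta^2. ``sensitivity`` has units 1/degree and
    ``curvature`` 1/degree^2. The rest class sits at the noise floor;
    intrinsic channels get half the angle sensitivity of extrinsic ones,
    mirroring the weaker position dependence of intrinsic hand muscles.
    """

    base_gain: np.ndarray  # (n_classes, n_channels), mV
    sensitivity: np.ndarray  # (n_classes, n_channels, 3), 1/deg
    curvature: np.ndarray  # (n_classes, n_channels, 3), 1/deg^2
    spectral_band_hz: tuple[float, float] = (30.0, 350.0)
    noise_floor: float = 0.01  # mV
    #: between-repetition effort variability of the active classes
    #: (grasp force is only held within a tolerance band): per-trial
    #: mean-one lognormal multipliers, one common + one per channel.
    #: The rest class has no voluntary contraction and gets neither.
    effort_sd: float = 0.05
    channel_sd: float = 0.025

    @staticmethod
    def default(
        n_extrinsic: int = 9,
        n_intrinsic: int = 4,
        classes: tuple[str, ...] = CLASSES,
        grid: PositionGrid | None = None,
    ) -> "ModulationParams":
        rng = np.random.default_rng(_PARAM_SEED)
        K = n_extrinsic + n_intrinsic
        C = len(classes)
        grid = grid or PositionGrid()
        end = np.asarray(grid.end_range_deg)

        # grasps share a common activation profile and differ by modest
        # per-channel deviations, so active classes overlap realistically
        # given window-level feature noise
        profile = rng.uniform(0.10, 0.30, size=K)
        delta = rng.uniform(-0.18, 0.18, size=(C, K))
        base = profile * (1.0 + delta)
        # rest: low-level postural tone, well below the grasps but above the
        # noise floor — holding a non-neutral wrist still takes muscle activity
        base[0] = rng.uniform(0.02, 0.05, size=K)

        # slopes/curvatures drawn in normalised angle (theta / end_range),
        # then converted to per-degree units
        alpha = rng.uniform(-0.6, 0.6, size=(C, K, 3))
        beta = rng.uniform(-0.3, 0.6, size=(C, K, 3))
        alpha[:, n_extrinsic:, :] *= 0.5  # intrinsic channels less affected
        beta[:, n_extrinsic:, :] *= 0.5
        sens = alpha / end
        curv = beta / end**2
        params = ModulationParams(base_gain=base, sensitivity=sens, curvature=curv)
        params.validate(grid)
        return params

    def gain(self, class_index: int, theta: np.ndarray) -> np.ndarray:
        """Per-channel amplitude (incl. noise floor) at wrist angles theta."""
        theta = np.asarray(theta, float)
        mult = (
            1.0
            + self.sensitivity[class_index] @ theta
            + self.curvature[class_index] @ (theta**2)
        )
        return self.base_gain[class_index] * mult + self.noise_floor

    def validate(self, grid: PositionGrid) -> None:
        for ci in range(self.base_gain.shape[0]):
            for p in grid.positions:
                if np.any(self.gain(ci, p.as_array()) <= 0):
                    raise ValueError("amplitude must stay positive on the grid")


@dataclass(frozen=True)
class SessionConfig:
    """Structure of one synthetic recording session."""

    n_channels_extrinsic: int = 9
    n_channels_intrinsic: int = 4
    fs_hz: float = 1000.0
    hold_s: float = 3.0
    reps_per_position: int = 6
    classes: tuple[str, ...] = CLASSES
    grid: PositionGrid = field(default_factory=PositionGrid)
    seed: int = 0
    modulation: ModulationParams | None = None
    jitter_deg: float = 5.0  # hold tolerance on the non-target DOFs

    def __post_init__(self):
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.hold_s <= 0:
            raise ValueError("hold_s must be positive")
        if self.reps_per_position < 1:
            raise ValueError("need at least one repetition")
        if self.n_channels_extrinsic + self.n_channels_intrinsic < 1:
            raise ValueError("need at least one channel")
        if len(self.classes) != 4:
            raise ValueError("the protocol has exactly 4 motion classes")
        if self.modulation is None:
            object.__setattr__(
                self,
                "modulation",
                ModulationParams.default(
                    self.n_channels_extrinsic,
                    self.n_channels_intrinsic,
                    self.classes,
                    self.grid,
                ),
            )

    @property
    def n_channels(self) -> int:
        return self.n_channels_extrinsic + self.n_channels_intrinsic

    @property
    def channel_groups(self) -> tuple[str, ...]:
        return ("extrinsic",) * self.n_channels_extrinsic + (
            "intrinsic",
        ) * self.n_channels_intrinsic

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.hold_s * self.fs_hz))


@dataclass
class EmgTrial:
    """One hold of one motion class in one wrist position."""

    signal: np.ndarray  # (n_channels, n_samples), mV
    gonio: np.ndarray  # (3, n_samples), degrees
    class_label: str
    position_index: int
    rep_index: int
    channel_groups: tuple[str, ...]
    fs_hz: float

    def __post_init__(self):
        if self.signal.shape[1] != self.gonio.shape[1]:
            raise ValueError("EMG and goniometer traces must share sample count")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _bandlimited_noise(
    rng: np.random.Generator, shape: tuple[int, int], fs: float, band
) -> np.ndarray:
    """Unit-variance Gaussian noise with all power inside ``band``.

    White noise is masked in the frequency domain (brick wall on the rFFT
    bins) and rescaled analytically so the expected sample variance is 1.
    """
    k, n = shape
    x = rng.standard_normal((k, n))
    X = np.fft.rfft(x, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    X *= mask
    y = np.fft.irfft(X, n=n, axis=1)
    # kept interior bins each carry 2/n of the unit variance
    w = np.full(f.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    var = (mask * w).sum() / n
    return y / np.sqrt(var)


def _smooth_jitter(
    rng: np.random.Generator, n: int, fs: float, amp_deg: float
) -> np.ndarray:
    """Slow zero-mean wobble, clipped to +/- amp_deg: (3, n)."""
    x = rng.standard_normal((3, n))
    X = np.fft.rfft(x, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (f > 0) & (f <= 1.0)  # <=1 Hz drift
    X *= mask
    y = np.fft.irfft(X, n=n, axis=1)
    s = y.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    y = y / s * (amp_deg / 3.0)
    return np.clip(y, -amp_deg, amp_deg)


def generate_session(config: SessionConfig) -> list[EmgTrial]:
    """Generate the full session: classes x 13 positions x repetitions.

    Deterministic: identical configs (including seed) give identical trials.
    """
    rng = np.random.default_rng(config.seed)
    n = config.samples_per_trial
    if n < 1:
        raise ValueError("hold too short for the sampling rate")
    mod = config.modulation
    trials: list[EmgTrial] = []
    for p_idx, pos in enumerate(config.grid.positions):
        theta = pos.as_array()
        for c_idx, label in enumerate(config.classes):
            amp = mod.gain(c_idx, theta)  # (K,)
            for rep in range(config.reps_per_position):
                if label == "rest":
                    effort = np.ones(config.n_channels)
                else:
                    # mean-one lognormal multipliers: exp(s*z - s^2/2)
                    e = np.exp(
                        mod.effort_sd * rng.standard_normal()
                        - mod.effort_sd**2 / 2.0
                    )
                    ck = np.exp(
                        mod.channel_sd * rng.standard_normal(config.n_channels)
                        - mod.channel_sd**2 / 2.0
                    )
                    effort = e * ck
                noise = _bandlimited_noise(
                    rng, (config.n_channels, n), config.fs_hz, mod.spectral_band_hz
                )
                signal = (amp * effort)[:, None] * noise
                gonio = theta[:, None] + _smooth_jitter(
                    rng, n, config.fs_hz, config.jitter_deg
                )
                trials.append(
                    EmgTrial(
                        signal=signal,
                        gonio=gonio,
                        class_label=label,
                        position_index=p_idx,
                        rep_index=rep,
                        channel_groups=config.channel_groups,
                        fs_hz=config.fs_hz,
                    )
                )
    return trials


def true_ratio(
    config: SessionConfig,
    class_label: str,
    channel: int,
    position: WristPosition,
) -> tuple[float, float]:
    """Analytic (mean_ratio, var_ratio) of amplitude-linear feature scale
    at ``position`` relative to neutral.

    The generator scales the whole signal by the amplitude, so features
    proportional to amplitude (MAV, WL) have mean ratio equal to the
    amplitude ratio and variance ratio equal to its square.
    """
    if class_label not in config.classes:
        raise KeyError(f"unknown class {class_label!r}")
    if not 0 <= channel < config.n_channels:
        raise KeyError(f"unknown channel {channel}")
    ci = config.classes.index(class_label)
    mod = config.modulation
    a = mod.gain(ci, position.as_array())[channel]
    a0 = mod.gain(ci, np.zeros(3))[channel]
    r = float(a / a0)
    return r, r * r


# --------------------------------------------------------------------------- #
# session I/O: one CSV per trial plus a JSON manifest


def _trial_filename(t: EmgTrial) -> str:
    return f"trial_p{t.position_index:02d}_{t.class_label}_r{t.rep_index}.csv"


def write_session(trials: list[EmgTrial], out_dir: str | Path, config: SessionConfig):
    """Write one CSV per trial and a manifest describing the session."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for t in trials:
        k = t.signal.shape[0]
        cols = {"sample": np.arange(t.n_samples)}
        for ch in range(k):
            cols[f"emg{ch + 1:02d}"] = t.signal[ch]
        for d, name in enumerate(DOF_NAMES):
            cols[name] = t.gonio[d]
        fname = _trial_filename(t)
        pd.DataFrame(cols).to_csv(out / fname, index=False, float_format="%.6g")
        records.append(
            {
                "file": fname,
                "class": t.class_label,
                "position_index": t.position_index,
                "rep_index": t.rep_index,
            }
        )
    manifest = {
        "fs_hz": config.fs_hz,
        "seed": config.seed,
        "classes": list(config.classes),
        "channel_groups": list(config.channel_groups),
        "grid_angles_deg": config.grid.angles().tolist(),
        "end_range_deg": list(config.grid.end_range_deg),
        "hold_s": config.hold_s,
        "reps_per_position": config.reps_per_position,
        "trials": records,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_session(in_dir: str | Path) -> tuple[list[EmgTrial], dict]:
    """Read a session written by :func:`write_session`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    groups = tuple(manifest["channel_groups"])
    k = len(groups)
    trials = []
    for rec in manifest["trials"]:
        df = pd.read_csv(src / rec["file"])
        signal = df[[f"emg{ch + 1:02d}" for ch in range(k)]].to_numpy().T
        gonio = df[list(DOF_NAMES)].to_numpy().T
        trials.append(
            EmgTrial(
                signal=signal,
                gonio=gonio,
                class_label=rec["class"],
                position_index=rec["position_index"],
                rep_index=rec["rep_index"],
                channel_groups=groups,
                fs_hz=manifest["fs_hz"],
            )
        )
    return trials, manifest
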