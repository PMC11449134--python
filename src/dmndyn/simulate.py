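"""Ground-truth LFP, event, and behavioral-corpus simulator.

The generator emulates a three-task stereo-EEG session: mind wandering (MW)
and alternate-uses (AUT) trials with a 20 s stimulus stage and a response
stage, plus short sustained-attention (ATT) trials, organized in three blocks
with stimulation flagged during block 2.  Per electrode the signal is

    1/f^alpha background noise  +  theta carrier  +  gamma carrier,

where each carrier is a constant-envelope oscillation whose instantaneous
frequency sweeps slowly across the band (so band power is distributed over
the band rather than concentrated at a tone) and whose amplitude follows the
planted percent-change trajectory of its (band, task, stage, subsystem)
cell, multiplicatively relative to the inter-trial baseline amplitude.  Two
measures make the planted trajectory the analytic expectation of the
downstream pipeline: (i) the background noise is spectrally suppressed
inside the two analysis bands, so the carrier is the only in-band content
and wavelet magnitude scales linearly with its amplitude; (ii) the carrier
is divided by the wavelet family's band-averaged tone response at its
instantaneous frequency, so the measured band magnitude is flat across the
sweep and the short pre-trial baseline window is a low-variance estimate of
the baseline level.  (A stochastic narrowband-noise carrier instead makes
the 0.4 s baseline a 1-2-sample Rayleigh average, whose inverse-moment bias
shifts every percent-change estimate by several points — see the methods
note.)  Within a probe, a band's channels share one frequency sweep with
independent phase offsets, so any linear re-reference of the probe remains
constant-envelope.  A separate :func:`pink_noise` generator provides
unsuppressed 1/f noise for spectral sanity checks.

Stimulation never alters the synthesized signals; its behavioral consequence
is planted directly in the response corpus as a shift of the cue-response
semantic distance in stimulation-block trials.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import VocabularyProvider
from .errors import ConfigurationError
from .io import Recording, validate_channels, validate_events
from .spectral import THETA_BAND, GAMMA_BAND, N_BINS, DEFAULT_WINDOWS

logger = logging.getLogger(__name__)

BANDS = {"theta": THETA_BAND, "gamma": GAMMA_BAND}
TASKS = ("MW", "AUT", "ATT")
STAGES = ("stimulus", "response")
SUBSYSTEMS = ("dorsomedial-DMN", "lateral-DMN")
ATT_CONDITIONS = ("target_only", "target_mask", "mask_only")


@dataclass(frozen=True)
class StimulationMetadata:
    """Stimulation parameters carried as metadata only; the signal generator
    never injects stimulation artifacts (behavioral effects are planted via
    :class:`GroundTruth`)."""

    frequency_hz: float = 130.0
    amplitude_ma: float = 4.0
    pulse_width_us: float = 180.0
    duty_cycle_s: tuple[float, float] = (3.0, 3.0)
    block: int = 2
    site: tuple[str, str] = ("", "")


@dataclass
class SimConfig:
    """Session layout and signal parameters; ``seed`` fully determines output."""

    n_subjects: int = 13
    n_probes_per_subject: int = 2
    contacts_per_probe: int = 4
    rate: float = 2000.0
    n_blocks: int = 3
    mw_per_block: int = 4
    aut_per_block: int = 4
    att_per_block: int = 8
    stimulus_s: float = 20.0
    response_s: float = 60.0
    iti_s: float = 2.0
    att_trial_s: float = 2.0
    lead_in_s: float = 6.0
    noise_exponent: float = 1.0
    noise_scale_uv: float = 20.0
    theta_amp_uv: float = 15.0
    gamma_amp_uv: float = 8.0
    stim_block: int = 2
    seed: int = 0

    def __post_init__(self):
        highest = max(hi for _, hi in BANDS.values())
        if self.rate <= 2.0 * highest:
            raise ConfigurationError(
                f"rate {self.rate} Hz must exceed twice the highest synthesized "
                f"frequency ({highest} Hz)")
        for name in ("n_subjects", "n_probes_per_subject", "contacts_per_probe",
                     "n_blocks", "mw_per_block", "aut_per_block"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.att_per_block < 0:
            raise ConfigurationError("att_per_block must be >= 0")
        span = DEFAULT_WINDOWS.t_end
        if min(self.stimulus_s, self.response_s) < span:
            raise ConfigurationError(
                f"stage durations must cover the {span:g} s analysis span")

    @property
    def trials_per_block(self) -> int:
        return self.mw_per_block + self.aut_per_block + self.att_per_block


@dataclass
class GroundTruth:
    """Machine-readable planted effects.

    ``band_profiles`` maps (band, task, stage, subsystem) to a length-29
    percent-change trajectory over time bins (absent cells mean no
    modulation).  Behavioral truth: cue-response semantic distances are drawn
    around ``originality_base`` and shifted by ``stim_originality_shift`` (per
    task) on stimulation-block trials.  ``attention_rates`` gives the
    button-press probability per ATT condition.
    """

    band_profiles: dict[tuple[str, str, str, str], np.ndarray] = field(default_factory=dict)
    attention_rates: dict[str, float] = field(
        default_factory=lambda: {"target_only": 0.70, "target_mask": 0.43, "mask_only": 0.20})
    originality_base: float = 0.95
    originality_sd: float = 0.02
    stim_originality_shift: dict[str, float] = field(
        default_factory=lambda: {"MW": 0.0, "AUT": 0.0})
    responses_per_trial: dict[str, int] = field(
        default_factory=lambda: {"MW": 2, "AUT": 4})
    absence_rate: float = 0.0
    n_bins: int = N_BINS

    def __post_init__(self):
        for key, traj in self.band_profiles.items():
            traj = np.asarray(traj, dtype=float)
            if traj.shape != (self.n_bins,):
                raise ConfigurationError(
                    f"profile {key} must have one value per time bin "
                    f"({self.n_bins}), got shape {traj.shape}")
            if (traj <= -100.0).any():
                raise ConfigurationError(f"profile {key} has percent change <= -100")
            self.band_profiles[key] = traj
        for cond, p in self.attention_rates.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"attention rate {cond}={p} outside [0, 1]")
        for task, shift in self.stim_originality_shift.items():
            if not (0.0 < self.originality_base + shift < 2.0):
                raise ConfigurationError(
                    f"planted shift for {task} pushes distances outside [0, 2]")

    @classmethod
    def from_constants(cls, cells: dict[tuple[str, str, str, str], float | np.ndarray],
                       n_bins: int = N_BINS, **kwargs) -> "GroundTruth":
        """Build profiles from {(band, task, stage, subsystem): level-or-trajectory};
        any key element may be "*" to broadcast over that axis."""
        axes = {"band": tuple(BANDS), "task": ("MW", "AUT"), "stage": STAGES,
                "subsystem": SUBSYSTEMS}
        profiles: dict[tuple[str, str, str, str], np.ndarray] = {}
        for (band, task, stage, subsys), value in cells.items():
            for b in (axes["band"] if band == "*" else (band,)):
                for t in (axes["task"] if task == "*" else (task,)):
                    for s in (axes["stage"] if stage == "*" else (stage,)):
                        for y in (axes["subsystem"] if subsys == "*" else (subsys,)):
                            traj = (np.full(n_bins, float(value))
                                    if np.isscalar(value) else np.asarray(value, float))
                            profiles[(b, t, s, y)] = traj
        return cls(band_profiles=profiles, n_bins=n_bins, **kwargs)

    def profile(self, band: str, task: str, stage: str, subsystem: str) -> np.ndarray:
        return self.band_profiles.get((band, task, stage, subsystem),
                                      np.zeros(self.n_bins))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "band_profiles": {"|".join(k): v.tolist() for k, v in self.band_profiles.items()},
            "attention_rates": self.attention_rates,
            "originality_base": self.originality_base,
            "originality_sd": self.originality_sd,
            "stim_originality_shift": self.stim_originality_shift,
            "responses_per_trial": self.responses_per_trial,
            "absence_rate": self.absence_rate,
            "n_bins": self.n_bins,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["band_profiles"] = {tuple(k.split("|")): np.asarray(v)
                              for k, v in d["band_profiles"].items()}
        return cls(**d)


def _spectrum_noise(n: int, rate: float, rng: np.random.Generator,
                    shape_fn) -> np.ndarray:
    """Gaussian noise built in the frequency domain with per-bin amplitude
    ``shape_fn(freqs)``; returned with unit standard deviation."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = np.asarray(shape_fn(freqs), dtype=float)
    amp[0] = 0.0
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, rate: float, exponent: float = 1.0,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Unit-SD 1/f^exponent noise (power spectral density ~ f^-exponent)."""
    rng = rng or np.random.default_rng()
    return _spectrum_noise(n, rate, rng, lambda f: _pink_shape(f, exponent))


def _pink_shape(f: np.ndarray, exponent: float) -> np.ndarray:
    amp = np.zeros_like(f)
    pos = f > 0
    amp[pos] = f[pos] ** (-exponent / 2.0)
    return amp


#: analysis wavelets have spectral SD f/n_cycles; background noise is removed
#: this many SDs beyond each band edge so no measurable noise leaks into the
#: band-averaged magnitude
SUPPRESS_MARGIN_SIGMAS = 3.0


def suppressed_bands(n_cycles: float = 7.0,
                     margin_sigmas: float = SUPPRESS_MARGIN_SIGMAS
                     ) -> list[tuple[float, float]]:
    return [(lo - margin_sigmas * lo / n_cycles, hi + margin_sigmas * hi / n_cycles)
            for lo, hi in BANDS.values()]


def _suppressed_pink(n: int, rate: float, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Pink noise with the theta and gamma analysis bands (plus a wavelet-
    bandwidth margin) spectrally removed, so planted carriers are the only
    content the band-averaged wavelet magnitude sees."""
    stop = suppressed_bands()

    def shape(f):
        amp = _pink_shape(f, exponent)
        for lo, hi in stop:
            amp[(f >= lo) & (f <= hi)] = 0.0
        return amp
    return _spectrum_noise(n, rate, rng, shape)


#: analysis sampling rate the tone-response compensation is computed at
ANALYSIS_RATE = 500.0

#: sweep stays this fraction inside the band edges; gamma additionally stays
#: below 58 Hz, clear of the 60 Hz line-noise notch
SWEEP_MARGIN = 0.10
SWEEP_RANGES = {"theta": (4.4, 7.6), "gamma": (34.0, 58.0)}


@lru_cache(maxsize=8)
def _band_response_grid(band: str) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged wavelet-magnitude response to a unit tone, on a fine
    frequency grid across the band (computed at the analysis rate)."""
    from .spectral import build_wavelet_family, _morlet_kernel
    lo, hi = BANDS[band]
    sub = build_wavelet_family().subset(lo, hi)
    f_grid = np.linspace(lo, hi, 200)
    R = np.zeros_like(f_grid)
    for f_k in sub.center_freqs:
        kern = _morlet_kernel(f_k, ANALYSIS_RATE, sub.n_cycles)
        m = np.arange(len(kern)) - len(kern) // 2
        R += 0.5 * np.abs(np.exp(-2j * np.pi * np.outer(f_grid, m) / ANALYSIS_RATE) @ kern)
    return f_grid, R / len(sub.center_freqs)


def _band_sweep(n: int, rate: float, band: str, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """One shared sweep for a probe: (cumulative phase, instantaneous freq).

    The instantaneous frequency oscillates slowly (0.05-0.2 Hz) across the
    band's sweep range, so the signal's power is spread over the band while
    staying quasi-stationary on the wavelet timescale.
    """
    lo, hi = SWEEP_RANGES[band]
    t = np.arange(n) / rate
    f_mod = rng.uniform(0.05, 0.2)
    f_inst = 0.5 * (lo + hi) + 0.5 * (hi - lo) * np.sin(
        2.0 * np.pi * f_mod * t + rng.uniform(0, 2 * np.pi))
    phase = 2.0 * np.pi * np.cumsum(f_inst) / rate
    return phase, f_inst


def _compensated_carrier(phase: np.ndarray, f_inst: np.ndarray, band: str,
                         rng: np.random.Generator) -> np.ndarray:
    """Constant-envelope carrier with a random phase offset, divided by the
    analysis family's tone response so the band-averaged wavelet magnitude is
    flat across the sweep (unit mean response)."""
    f_grid, R = _band_response_grid(band)
    Rn = np.interp(f_inst, f_grid, R / R.mean())
    return np.cos(phase + rng.uniform(0, 2 * np.pi)) / Rn


def spectral_slope(x: np.ndarray, rate: float, f_lo: float = 2.0,
                   f_hi: float = 100.0) -> float:
    """Log-log slope of the Welch power spectrum between f_lo and f_hi;
    approximately -noise_exponent for 1/f^exponent noise."""
    from scipy.signal import welch
    f, pxx = welch(np.asarray(x, float), fs=rate, nperseg=min(len(x), 4096))
    sel = (f >= f_lo) & (f <= f_hi) & (pxx > 0)
    coef = np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)
    return float(coef[0])


def make_events(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One session's trial/stage rows.  Trial order is shuffled within block;
    MW/AUT trials have a stimulus and a response stage, ATT trials a single
    short stimulus stage.  Stimulation is flagged throughout ``stim_block``."""
    rows = []
    t = cfg.lead_in_s
    trial_id = 0
    for block in range(1, cfg.n_blocks + 1):
        tasks = (["MW"] * cfg.mw_per_block + ["AUT"] * cfg.aut_per_block
                 + ["ATT"] * cfg.att_per_block)
        rng.shuffle(tasks)
        for task in tasks:
            trial_id += 1
            stim = int(block == cfg.stim_block)
            if task == "ATT":
                rows.append((trial_id, task, block, stim, "stimulus", t, cfg.att_trial_s))
                t += cfg.att_trial_s + cfg.iti_s
            else:
                rows.append((trial_id, task, block, stim, "stimulus", t, cfg.stimulus_s))
                t += cfg.stimulus_s
                rows.append((trial_id, task, block, stim, "response", t, cfg.response_s))
                t += cfg.response_s + cfg.iti_s
    df = pd.DataFrame(rows, columns=["trial_id", "task", "block", "stim",
                                     "stage", "onset_s", "duration_s"])
    return validate_events(df)


def make_channels(cfg: SimConfig, subject: str) -> pd.DataFrame:
    """Channel table for one subject: probes alternate between the two DMN
    subsystems; each probe ends in a white-matter-like reference contact."""
    regions = {"dorsomedial-DMN": "anterior cingulate", "lateral-DMN": "middle temporal gyrus"}
    rows = []
    for p in range(cfg.n_probes_per_subject):
        subsystem = SUBSYSTEMS[p % 2]
        probe = f"{subject}P{p}"
        base = np.array([20.0 * (1 if subsystem == "lateral-DMN" else -1), 10.0 * p, 0.0])
        for c in range(cfg.contacts_per_probe):
            coord = base + np.array([0.0, 0.0, 3.5 * c])
            rows.append((f"{probe}C{c}", probe, c, *coord, "default", subsystem,
                         "ok", "", regions[subsystem]))
        coord = base + np.array([0.0, 0.0, 3.5 * cfg.contacts_per_probe])
        rows.append((f"{probe}Cref", probe, cfg.contacts_per_probe, *coord,
                     "unassigned", "none", "excluded", "reference", ""))
    df = pd.DataFrame(rows, columns=["channel_id", "probe_id", "contact_index",
                                     "x_mni", "y_mni", "z_mni", "network",
                                     "subsystem", "status", "status_reason", "region"])
    return validate_channels(df)


def _gain_envelope(n: int, rate: float, events: pd.DataFrame, truth: GroundTruth,
                   band: str, subsystem: str) -> np.ndarray:
    """Multiplicative amplitude gain over the whole session for one carrier.

    Inside each MW/AUT stage the gain follows 1 + profile/100, linearly
    interpolated through the bin centres and held flat beyond them; everywhere
    else (baselines, ITIs, ATT trials) the gain is 1, so the planted change is
    expressed relative to the pre-trial baseline amplitude.
    """
    gain = np.ones(n)
    centers = DEFAULT_WINDOWS.centers
    for _, ev in events.iterrows():
        if ev["task"] not in ("MW", "AUT"):
            continue
        prof = truth.profile(band, ev["task"], ev["stage"], subsystem)
        if not prof.any():
            continue
        i0 = int(round(ev["onset_s"] * rate))
        i1 = min(int(round((ev["onset_s"] + ev["duration_s"]) * rate)), n)
        t_rel = np.arange(i1 - i0) / rate
        gain[i0:i1] = np.interp(t_rel, centers, 1.0 + prof / 100.0)
    return gain


def simulate_recording(cfg: SimConfig, truth: GroundTruth, subject_index: int = 0
                       ) -> tuple[Recording, pd.DataFrame, pd.DataFrame]:
    """Synthesize one subject's session: (Recording, TrialEvents, ChannelTable)."""
    subject = f"S{subject_index + 1:02d}"
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_index]))
    events = make_events(cfg, rng)
    channels = make_channels(cfg, subject)
    last = events.iloc[-1]
    n = int(np.ceil((last["onset_s"] + last["duration_s"] + cfg.lead_in_s) * cfg.rate))

    amps = {"theta": cfg.theta_amp_uv, "gamma": cfg.gamma_amp_uv}
    samples = np.empty((len(channels), n))
    envelopes = {subsys: {band: _gain_envelope(n, cfg.rate, events, truth, band, subsys)
                          for band in BANDS}
                 for subsys in SUBSYSTEMS}
    sweeps = {(probe, band): _band_sweep(n, cfg.rate, band, rng)
              for probe in channels["probe_id"].unique() for band in BANDS}
    for i, ch in channels.iterrows():
        if ch["status_reason"] == "reference":
            samples[i] = 0.1 * cfg.noise_scale_uv * rng.standard_normal(n)
            continue
        sig = cfg.noise_scale_uv * _suppressed_pink(n, cfg.rate, cfg.noise_exponent, rng)
        for band in BANDS:
            phase, f_inst = sweeps[(ch["probe_id"], band)]
            carrier = _compensated_carrier(phase, f_inst, band, rng)
            if ch["subsystem"] in SUBSYSTEMS:
                carrier = envelopes[ch["subsystem"]][band] * carrier
            sig = sig + amps[band] * carrier
        samples[i] = sig
    rec = Recording(samples, cfg.rate, channels["channel_id"].tolist())
    return rec, events, channels


def simulate_cohort(cfg: SimConfig, truth: GroundTruth):
    """Yield (subject, Recording, TrialEvents, ChannelTable) per subject."""
    for s in range(cfg.n_subjects):
        rec, events, channels = simulate_recording(cfg, truth, subject_index=s)
        yield f"S{s + 1:02d}", rec, events, channels


ABSENCE_TEXT = "nothing comes to mind"


def simulate_response_corpus(cfg: SimConfig, truth: GroundTruth,
                             dim: int = 32) -> tuple[pd.DataFrame, VocabularyProvider]:
    """Synthetic free-response corpus with planted cue-response distances.

    Every response is a short phrase whose single content token maps, under
    the returned vocabulary provider, to a vector at an exactly planted cosine
    distance from its cue token's vector: d ~ Normal(base + shift, sd), where
    the shift applies only to stimulation-block trials of the shifted task.
    Filler "absence of thought" rows exercise the exclusion rule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]))
    vectors: dict[str, np.ndarray] = {}

    def unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    items = {"MW": [f"shape{b}_{k}" for b in range(1, cfg.n_blocks + 1)
                    for k in range(cfg.mw_per_block)],
             "AUT": [f"object{b}_{k}" for b in range(1, cfg.n_blocks + 1)
                     for k in range(cfg.aut_per_block)]}
    for task in ("MW", "AUT"):
        for tok in items[task]:
            vectors[tok] = unit(rng.standard_normal(dim))

    rows = []
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:02d}"
        for task in ("MW", "AUT"):
            per_block = cfg.mw_per_block if task == "MW" else cfg.aut_per_block
            for block in range(1, cfg.n_blocks + 1):
                stim = int(block == cfg.stim_block)
                shift = truth.stim_originality_shift.get(task, 0.0) if stim else 0.0
                for k in range(per_block):
                    item = items[task][(block - 1) * per_block + k]
                    u = vectors[item]
                    for r in range(truth.responses_per_trial.get(task, 1)):
                        d = float(np.clip(rng.normal(truth.originality_base + shift,
                                                     truth.originality_sd), 0.005, 1.995))
                        w = rng.standard_normal(dim)
                        w = unit(w - (w @ u) * u)
                        cos = 1.0 - d
                        rtok = f"r_{subject.lower()}_{item}_{r}"
                        vectors[rtok] = cos * u + np.sqrt(1.0 - cos ** 2) * w
                        rows.append((subject, item, task, block, stim,
                                     f"use it as a {rtok}"))
                    if rng.random() < truth.absence_rate:
                        rows.append((subject, item, task, block, stim, ABSENCE_TEXT))
    responses = pd.DataFrame(rows, columns=["subject", "item", "task", "block",
                                            "stim", "response"])
    return responses, VocabularyProvider(vectors, name="planted-synthetic")


def simulate_attention_behavior(cfg: SimConfig, truth: GroundTruth,
                                n_trials_per_condition: int | None = None
                                ) -> pd.DataFrame:
    """Bernoulli button-press outcomes for the sustained-attention task.

    By default the session layout fixes trial counts (ATT trials split
    3/8 target-only, 3/8 target+mask, 2/8 mask-only, as in the 75%-target
    design); ``n_trials_per_condition`` overrides for rate-recovery checks.
    Response latencies are uniform on (0.2, 1.5) s.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1299709]))
    rows = []
    for s in range(cfg.n_subjects):
        subject = f"S{s + 1:02d}"
        if n_trials_per_condition is None:
            n_att = cfg.att_per_block * cfg.n_blocks
            counts = {"target_only": int(round(0.375 * n_att)),
                      "target_mask": int(round(0.375 * n_att))}
            counts["mask_only"] = n_att - sum(counts.values())
        else:
            counts = {c: n_trials_per_condition for c in ATT_CONDITIONS}
        for cond in ATT_CONDITIONS:
            p = truth.attention_rates[cond]
            for _ in range(counts[cond]):
                reported = int(rng.random() < p)
                latency = float(rng.uniform(0.2, 1.5)) if reported else np.nan
                rows.append((subject, cond, reported, latency))
    return pd.DataFrame(rows, columns=["subject", "condition", "reported", "latency_s"])
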