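"""Synthetic fixture generators with planted ground truth.

Every generator is deterministic under a fixed seed and returns, alongside
the simulated measurement, the ground-truth labels needed to score the
downstream analysis stage that consumes it:

* :func:`generate_count_matrix` — a gene-by-nucleus negative-binomial count
  matrix with planted cell types, per-type marker genes, library-size
  variation, a mitochondrial gene block, and a first-/second-order
  retrograde-label (XFP) mixture.
* :func:`generate_cell_attached_trace` — a loose-seal cell-attached style
  voltage trace containing negative-going spike templates of known half
  width at Poisson times.
* :func:`generate_whole_cell_sweeps` — current-clamp step sweeps: ohmic
  (exponential-approach) responses to hyperpolarizing steps and
  leaky-integrate-and-fire spiking for depolarizing steps.
* :func:`generate_axon_image` — 8-bit images with constant-intensity blob
  signal over bounded background noise, optionally two channels plus a
  label-mask set with a planted colocalization fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData

__all__ = [
    "AtlasSimConfig",
    "EphysSimConfig",
    "ImageSimConfig",
    "generate_count_matrix",
    "generate_cell_attached_trace",
    "generate_whole_cell_sweeps",
    "generate_axon_image",
    "lif_expected_spike_count",
    "spike_template",
    "write_count_matrix",
    "write_trace",
    "write_image",
]

_N_MITO_GENES = 13  # mouse mitochondrial genome encodes 13 protein-coding genes
_ROI_CYCLE = ("M1M2S1", "RFA", "S2", "HY", "MB", "CB", "PONS", "MED")


@dataclass
class AtlasSimConfig:
    """Conditions for the simulated labeled-nucleus atlas.

    ``marker_logfc`` is a natural-log fold change applied to each type's
    marker genes. ``xfp_rate_*`` are the per-nucleus probabilities of
    carrying at least one XFP transcript for directly (first-order) and
    indirectly (second-order) labeled populations.
    """

    n_types: int = 12
    nuclei_per_type: int = 300
    n_genes: int = 2000
    n_marker_genes_per_type: int = 20
    marker_logfc: float = 1.0
    library_size_mean: float = 10000.0
    xfp_rate_first_order: float = 0.8
    xfp_rate_second_order: float = 0.02
    frac_second_order_types: float = 0.25
    mito_frac_mean: float = 0.02
    nb_dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.n_genes < 1 or self.nuclei_per_type < 1:
            raise ValueError("n_types, n_genes and nuclei_per_type must be positive")
        for name in ("xfp_rate_first_order", "xfp_rate_second_order",
                     "frac_second_order_types", "mito_frac_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        needed = _N_MITO_GENES + self.n_types * self.n_marker_genes_per_type
        if needed > self.n_genes:
            raise ValueError(
                f"need {needed} genes for disjoint marker sets plus the "
                f"mitochondrial block but n_genes={self.n_genes}"
            )
        if self.library_size_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("library_size_mean and nb_dispersion must be positive")


@dataclass
class EphysSimConfig:
    """Conditions for simulated recordings (20 kHz sampling by default)."""

    sampling_rate: float = 20000.0
    spike_amplitude: float = 5.0      # mV, magnitude of the negative peak
    spike_half_width_true: float = 1.0  # ms
    firing_rate_true: float = 2.5     # Hz
    input_resistance_true: float = 100.0  # MOhm
    noise_sd: float = 0.2             # mV
    v_rest: float = -65.0             # mV
    membrane_tau: float = 0.020       # s
    spike_threshold: float = -45.0    # mV, LIF threshold for whole-cell sweeps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.spike_half_width_true < 5.0:
            raise ValueError("spike_half_width_true must be in (0, 5) ms")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.firing_rate_true < 0:
            raise ValueError("firing_rate_true must be non-negative")


@dataclass
class ImageSimConfig:
    """Conditions for simulated axon-signal images."""

    height: int = 512
    width: int = 512
    n_blobs: int = 10
    blob_intensity: int = 200
    background_sd: float = 20.0
    blob_radius: int = 6
    coloc_fraction_true: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 100 or self.width < 100:
            raise ValueError("image dimensions must be >= 100 px")
        if not 0 <= self.blob_intensity <= 255:
            raise ValueError("blob_intensity must be an 8-bit value")
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")
        if not 0.0 <= self.coloc_fraction_true <= 1.0:
            raise ValueError("coloc_fraction_true must be in [0, 1]")


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def generate_count_matrix(cfg: AtlasSimConfig) -> AnnData:
    """Simulate a labeled-nucleus count matrix with planted type structure.

    Counts are negative binomial (gamma–Poisson) with gene-specific relative
    abundances, a shared dispersion, and lognormal library sizes. Each type
    up-regulates its own disjoint marker-gene block by ``exp(marker_logfc)``.
    The last ``round(frac_second_order_types * n_types)`` types are planted
    as second-order (indirectly labeled); XFP transcript counts are
    zero-inflated Poisson with the Bernoulli rate set by order status.

    Returns an :class:`~anndata.AnnData` (nuclei x genes) whose ``obs``
    carries ``type_true``, ``order_true``, ``roi_label``, ``sort_channel``,
    ``xfp_count``, ``mito_fraction`` and ``genes_detected``, and whose
    ``uns['ground_truth']`` records marker sets, per-type order status and
    sort-channel probabilities.
    """
    rng = np.random.default_rng(cfg.seed)
    n_nuclei = cfg.n_types * cfg.nuclei_per_type

    gene_names = [f"mt-Gene{i + 1}" for i in range(_N_MITO_GENES)]
    gene_names += [f"Gene{i + 1:05d}" for i in range(cfg.n_genes - _N_MITO_GENES)]

    # gene relative abundances: lognormal, mito block pinned to its target share
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
    rel[:_N_MITO_GENES] = 0.0
    rel /= rel.sum()
    rel *= 1.0 - cfg.mito_frac_mean
    if cfg.mito_frac_mean > 0:
        mito_rel = rng.lognormal(mean=0.0, sigma=0.3, size=_N_MITO_GENES)
        rel[:_N_MITO_GENES] = mito_rel / mito_rel.sum() * cfg.mito_frac_mean

    m = cfg.n_marker_genes_per_type
    marker_sets: dict[str, list[str]] = {}
    n_second = int(round(cfg.frac_second_order_types * cfg.n_types))
    type_names = [f"T{t:02d}" for t in range(cfg.n_types)]
    order_true = {
        name: ("second" if t >= cfg.n_types - n_second else "first")
        for t, name in enumerate(type_names)
    }
    roi_of_type = {name: _ROI_CYCLE[t % len(_ROI_CYCLE)]
                   for t, name in enumerate(type_names)}

    lib = rng.lognormal(mean=np.log(cfg.library_size_mean) - 0.3 ** 2 / 2,
                        sigma=0.3, size=n_nuclei)

    counts = np.empty((n_nuclei, cfg.n_genes), dtype=np.int32)
    type_labels = np.repeat(type_names, cfg.nuclei_per_type)
    for t, name in enumerate(type_names):
        prof = rel.copy()
        lo = _N_MITO_GENES + t * m
        marker_idx = np.arange(lo, lo + m)
        prof[marker_idx] *= np.exp(cfg.marker_logfc)
        prof /= prof.sum()
        marker_sets[name] = [gene_names[i] for i in marker_idx]
        rows = slice(t * cfg.nuclei_per_type, (t + 1) * cfg.nuclei_per_type)
        mean = lib[rows, None] * prof[None, :]
        lam = rng.gamma(shape=cfg.nb_dispersion, scale=mean / cfg.nb_dispersion)
        counts[rows] = rng.poisson(lam).astype(np.int32)

    # XFP transcript counts: Bernoulli(order rate) x (1 + Poisson)
    rates = np.where(
        np.vectorize(order_true.get)(type_labels) == "first",
        cfg.xfp_rate_first_order, cfg.xfp_rate_second_order,
    )
    xfp = rng.binomial(1, rates) * (1 + rng.poisson(2.0, size=n_nuclei))

    # per-type projection-channel composition (planted, Dirichlet-distributed)
    channel_probs = {name: rng.dirichlet([4.0, 2.0, 2.0]) for name in type_names}
    channels = np.empty(n_nuclei, dtype=object)
    labels3 = np.array(["GFP", "dual", "mScarlet"])
    for name in type_names:
        sel = type_labels == name
        channels[sel] = rng.choice(labels3, size=sel.sum(), p=channel_probs[name])

    totals = counts.sum(axis=1)
    mito_counts = counts[:, :_N_MITO_GENES].sum(axis=1)
    obs = pd.DataFrame(
        {
            "type_true": pd.Categorical(type_labels),
            "order_true": pd.Categorical([order_true[t] for t in type_labels]),
            "roi_label": pd.Categorical([roi_of_type[t] for t in type_labels]),
            "sort_channel": pd.Categorical(channels.astype(str)),
            "xfp_count": xfp.astype(np.int64),
            "total_counts": totals.astype(np.int64),
            "mito_fraction": np.divide(mito_counts, totals,
                                       out=np.zeros(n_nuclei), where=totals > 0),
            "genes_detected": (counts > 0).sum(axis=1).astype(np.int64),
        },
        index=[f"nucleus_{i:06d}" for i in range(n_nuclei)],
    )
    adata = AnnData(X=counts, obs=obs, var=pd.DataFrame(index=gene_names))
    adata.var["mito"] = adata.var_names.str.startswith("mt-")
    adata.uns["ground_truth"] = {
        "marker_genes": marker_sets,
        "type_order": order_true,
        "roi_of_type": roi_of_type,
        "channel_probs": {k: v.tolist() for k, v in channel_probs.items()},
        "config": asdict(cfg),
    }
    return adata


# ---------------------------------------------------------------------------
# cell-attached trace
# ---------------------------------------------------------------------------

def spike_template(half_width_ms: float, sampling_rate: float,
                   amplitude: float = 1.0) -> np.ndarray:
    """Negative difference-of-exponentials transient of given half width.

    The continuous template ``-(exp(-t/5) - exp(-t))`` is rescaled in time so
    that its full width at half of the (negative) peak equals
    ``half_width_ms``, then sampled at ``sampling_rate`` and normalized so
    the sampled minimum is exactly ``-amplitude``.
    """
    tau_r, tau_d = 1.0, 5.0
    t = np.linspace(0.0, 40.0, 40001)
    f = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    f /= f.max()
    above = f >= 0.5
    i0, i1 = np.argmax(above), len(above) - np.argmax(above[::-1]) - 1
    # linear interpolation of the 0.5 crossings in template time units
    lo = np.interp(0.5, [f[i0 - 1], f[i0]], [t[i0 - 1], t[i0]])
    hi = np.interp(0.5, [f[i1 + 1], f[i1]], [t[i1 + 1], t[i1]])
    scale = half_width_ms / (hi - lo)          # ms per template unit
    dt_ms = 1000.0 / sampling_rate
    dur_ms = min(40.0 * scale, 8.0)
    ts = np.arange(0.0, dur_ms, dt_ms) / scale
    tmpl = -(np.exp(-ts / tau_d) - np.exp(-ts / tau_r))
    tmpl /= np.abs(tmpl.min())
    return amplitude * tmpl


def generate_cell_attached_trace(
    cfg: EphysSimConfig, duration_s: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a cell-attached style trace with spikes at Poisson times.

    Returns ``(trace, spike_times_s)`` where ``spike_times_s`` are the onset
    times of the inserted templates. Spikes closer than 12 ms to an already
    accepted spike are thinned so every planted spike is isolated within the
    +/-5 ms analysis window. Raises if the requested rate makes such
    isolation impossible.
    """
    if duration_s < 10.0:
        raise ValueError("trace must be at least 10 s for rate analysis")
    if cfg.firing_rate_true >= 100.0:
        raise ValueError(
            "firing_rate_true too high: +/-5 ms isolation windows must overlap"
        )
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * cfg.sampling_rate))
    trace = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)

    if cfg.firing_rate_true == 0:
        return trace, np.array([])

    tmpl = spike_template(cfg.spike_half_width_true, cfg.sampling_rate,
                          cfg.spike_amplitude)
    margin = (len(tmpl) + 1) / cfg.sampling_rate
    n_spk = rng.poisson(cfg.firing_rate_true * duration_s)
    raw = np.sort(rng.uniform(0.006, duration_s - margin, size=n_spk))
    kept: list[float] = []
    for t_s in raw:
        if not kept or t_s - kept[-1] > 0.012:
            kept.append(t_s)
    times = np.asarray(kept)
    for t_s in times:
        i = int(round(t_s * cfg.sampling_rate))
        trace[i:i + len(tmpl)] += tmpl[: n - i]
    return trace, times


# ---------------------------------------------------------------------------
# whole-cell sweeps
# ---------------------------------------------------------------------------

_AP_RISE_MS = 0.4     # threshold -> peak
_AP_FALL_MS = 1.0     # peak -> trough
_AP_RECOVER_MS = 1.0  # trough -> reset
_AP_PEAK_MV = 20.0
_AP_TROUGH_MV = -70.0


def _ap_waveform(threshold: float, reset: float, sampling_rate: float) -> np.ndarray:
    """Stereotyped AP inserted at LIF threshold crossings (piecewise linear)."""
    dt_ms = 1000.0 / sampling_rate
    rise = np.linspace(threshold, _AP_PEAK_MV, max(int(_AP_RISE_MS / dt_ms), 2))
    fall = np.linspace(_AP_PEAK_MV, _AP_TROUGH_MV,
                       max(int(_AP_FALL_MS / dt_ms), 2))[1:]
    rec = np.linspace(_AP_TROUGH_MV, reset,
                      max(int(_AP_RECOVER_MS / dt_ms), 2))[1:]
    return np.concatenate([rise, fall, rec])


def lif_expected_spike_count(cfg: EphysSimConfig, current_pa: float,
                             duration_s: float) -> int:
    """Closed-form noise-free spike count of the simulated LIF cell.

    The drive is ``D = I * R`` (mV); with threshold distance
    ``Th = spike_threshold - v_rest`` the first spike occurs at
    ``tau * ln(D / (D - Th))`` and subsequent spikes follow every
    ``t_ap + tau * ln(D / (D - Th))`` where ``t_ap`` is the stereotyped AP
    insertion time. Returns 0 for subthreshold drive.
    """
    drive = current_pa * cfg.input_resistance_true * 1e-3  # mV
    th = cfg.spike_threshold - cfg.v_rest
    if drive <= th:
        return 0
    t_first = cfg.membrane_tau * np.log(drive / (drive - th))
    n_ap = len(_ap_waveform(cfg.spike_threshold, cfg.v_rest, cfg.sampling_rate))
    t_ap = n_ap / cfg.sampling_rate
    isi = t_ap + t_first
    if t_first > duration_s:
        return 0
    return 1 + int(np.floor((duration_s - t_first) / isi))


def generate_whole_cell_sweeps(
    cfg: EphysSimConfig, protocol: list[tuple[float, float]]
) -> dict:
    """Simulate current-clamp step sweeps for a ``(current pA, duration s)`` protocol.

    Subthreshold steps produce an ohmic exponential approach
    ``V = v_rest + I * R * (1 - exp(-t/tau))`` plus Gaussian noise; supra-
    threshold depolarizing steps produce leaky-integrate-and-fire spiking
    with a stereotyped AP waveform inserted at each threshold crossing.

    Returns a dict with ``time_s``, ``sweeps`` (one trace per protocol step),
    ``currents_pa`` and a ``ground_truth`` record (true R, rest, threshold
    and per-step noise-free spike counts).
    """
    if not protocol:
        raise ValueError("protocol must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    sweeps, currents = [], []
    true_counts = []
    ap = _ap_waveform(cfg.spike_threshold, cfg.v_rest, fs)
    for current_pa, dur_s in protocol:
        n = int(round(dur_s * fs))
        t = np.arange(n) / fs
        drive = current_pa * cfg.input_resistance_true * 1e-3  # mV
        v = cfg.v_rest + drive * (1.0 - np.exp(-t / cfg.membrane_tau))
        if drive > cfg.spike_threshold - cfg.v_rest:
            v = np.full(n, cfg.v_rest)
            i = 0
            v_cur = cfg.v_rest
            while i < n:
                # analytic time to threshold from v_cur under constant drive
                target = cfg.v_rest + drive
                gap = target - v_cur
                th_gap = target - cfg.spike_threshold
                dt_th = cfg.membrane_tau * np.log(gap / th_gap)
                j = i + int(np.ceil(dt_th * fs))
                seg = np.arange(i, min(j, n)) - i
                v[i:min(j, n)] = target - gap * np.exp(-seg / (cfg.membrane_tau * fs))
                if j >= n:
                    break
                k = min(j + len(ap), n)
                v[j:k] = ap[: k - j]
                i = k
                v_cur = cfg.v_rest
        if cfg.noise_sd > 0:
            v = v + rng.normal(0.0, cfg.noise_sd, size=n)
        sweeps.append(v)
        currents.append(current_pa)
        true_counts.append(lif_expected_spike_count(cfg, current_pa, dur_s))
    return {
        "time_s": [np.arange(len(s)) / fs for s in sweeps],
        "sweeps": sweeps,
        "currents_pa": np.asarray(currents, dtype=float),
        "ground_truth": {
            "input_resistance_mohm": cfg.input_resistance_true,
            "v_rest_mv": cfg.v_rest,
            "threshold_mv": cfg.spike_threshold,
            "spike_counts": true_counts,
        },
    }


# ---------------------------------------------------------------------------
# axon images
# ---------------------------------------------------------------------------

def generate_axon_image(cfg: ImageSimConfig, two_channel: bool = False):
    """Simulate 8-bit axon-signal images.

    Single-channel mode returns ``(image, truth)`` where ``truth`` holds the
    blob mask. Background noise is folded-normal clipped at three standard
    deviations, so with ``background_sd <= 39`` it never reaches the default
    binarization threshold of 120; blob pixels have constant intensity
    ``blob_intensity``.

    Two-channel mode returns ``(ch1, ch2, mask_labels, truth)``: ``ch1`` is
    bright inside every mask, ``ch2`` only inside the planted colocalized
    subset (Bernoulli ``coloc_fraction_true`` per mask); ``mask_labels`` is
    an integer label image (0 = background, masks numbered from 1).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.height, cfg.width)

    def background() -> np.ndarray:
        if cfg.background_sd == 0:
            return np.zeros(shape)
        b = np.abs(rng.normal(0.0, cfg.background_sd, size=shape))
        return np.clip(b, 0.0, 3.0 * cfg.background_sd)

    r = cfg.blob_radius
    yy, xx = np.ogrid[: cfg.height, : cfg.width]

    def disk(cy: int, cx: int) -> np.ndarray:
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2

    # non-overlapping centers on a jittered grid
    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < cfg.n_blobs and attempts < 10000:
        cy = int(rng.integers(r + 2, cfg.height - r - 2))
        cx = int(rng.integers(r + 2, cfg.width - r - 2))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (3 * r) ** 2 for y, x in centers):
            centers.append((cy, cx))
        attempts += 1
    if len(centers) < cfg.n_blobs:
        raise ValueError("could not place requested number of blobs without overlap")

    blob_mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(centers):
        d = disk(cy, cx)
        blob_mask |= d
        labels[d] = i + 1

    def compose(mask: np.ndarray) -> np.ndarray:
        img = background()
        img[mask] = cfg.blob_intensity
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    if not two_channel:
        truth = {"blob_mask": blob_mask, "centers": centers}
        return compose(blob_mask), truth

    coloc = rng.random(cfg.n_blobs) < cfg.coloc_fraction_true
    ch2_mask = np.zeros(shape, dtype=bool)
    for i, (cy, cx) in enumerate(centers):
        if coloc[i]:
            ch2_mask |= disk(cy, cx)
    truth = {
        "blob_mask": blob_mask,
        "centers": centers,
        "coloc_positive": coloc,
    }
    return compose(blob_mask), compose(ch2_mask), labels, truth


# ---------------------------------------------------------------------------
# writers (text and standard formats)
# ---------------------------------------------------------------------------

def write_count_matrix(adata: AnnData, outdir: str | Path) -> None:
    """Write MTX + genes/barcodes TSV + metadata TSV + ground-truth JSON."""
    from scipy import io as sio
    from scipy import sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(outdir / "matrix.mtx"), sparse.csr_matrix(adata.X).T)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      header=False, index=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    adata.obs.to_csv(outdir / "metadata.tsv", sep="\t")
    gt = adata.uns.get("ground_truth")
    if gt is not None:
        (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))


def write_trace(trace: np.ndarray, sampling_rate: float, path: str | Path) -> None:
    """Write a trace as a two-column delimited file (time s, value)."""
    t = np.arange(len(trace)) / sampling_rate
    np.savetxt(path, np.column_stack([t, trace]), delimiter="\t",
               header="time_s\tvalue", comments="")


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit image (or stack of channels) as TIFF."""
    import tifffile

    tifffile.imwrite(str(path), img)
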