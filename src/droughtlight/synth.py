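"""Synthetic data generators with known ground truth.

Every generator returns its output together with a :class:`SimTruth` record
holding the parameters that downstream estimators are expected to recover:
analytic OJIP landmarks for fluorescence traces, planted DEG labels and
signed log2 fold changes for count matrices, planted motif sites for
promoter sets, and true fold changes for qPCR plates.

The generators are phenomenological: the OJIP trace is a sum of saturating
exponentials plus a log-normal-shaped K-band bump, not a kinetic model of
PSII electron transport.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .ojip import LANDMARK_TIMES, FluorescenceTransient

# centre of the K-band bump (seconds) and its width in ln-time units;
# sigma 0.35 keeps the bump local to ~0.15-0.6 ms
K_BAND_TIME = 3e-4
K_BAND_SIGMA = 0.35

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted by a simulator call."""

    generator: str
    params: dict
    seed: int


@dataclass(frozen=True)
class TransientSpec:
    """Parameters of one synthetic OJIP fluorescence rise.

    The noise-free model is

        F(t) = f0 + (fm - f0) * sum_k amp_k * (1 - exp(-t / tau_k))
             + k_band_amp * (fm - f0) * exp(-(ln t - ln 3e-4)^2 / (2 sigma_K^2))

    sampled on a log-spaced grid that always contains the four landmark
    times (50 us, 300 us, 2 ms, 30 ms) exactly, with multiplicative
    Gaussian noise of relative standard deviation ``noise_sd``.
    """

    f0: float = 500.0
    fm: float = 2500.0
    amp_oj: float = 0.5
    amp_ji: float = 0.3
    amp_ip: float = 0.2
    tau_oj: float = 4e-4
    tau_ji: float = 8e-3
    tau_ip: float = 8e-2
    k_band_amp: float = 0.0
    noise_sd: float = 0.0
    n_points: int = 120
    t_min: float = 1e-5
    t_max: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        amps = (self.amp_oj, self.amp_ji, self.amp_ip)
        if any(a < 0 for a in amps):
            raise ValidationError("phase amplitudes must be >= 0")
        if abs(sum(amps) - 1.0) > 1e-9:
            raise ValidationError(
                f"phase amplitudes must sum to 1, got {sum(amps)!r}"
            )
        if not (self.tau_oj < self.tau_ji < self.tau_ip):
            raise ValidationError("time constants must satisfy tau_oj < tau_ji < tau_ip")
        if not 0 < self.f0 < self.fm:
            raise ValidationError("require 0 < f0 < fm")
        if self.k_band_amp < 0:
            raise ValidationError("k_band_amp must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (self.t_min < K_BAND_TIME < self.t_max):
            raise ValidationError("grid must bracket the K-band time 3e-4 s")
        if not (self.t_min <= min(LANDMARK_TIMES.values())
                and self.t_max >= max(LANDMARK_TIMES.values())):
            raise ValidationError("grid must span all landmark times")
        if self.n_points < 16:
            raise ValidationError("n_points must be >= 16")


def stress_spec(base: TransientSpec | None = None) -> TransientSpec:
    """Default "prolonged drought" preset.

    FM is depressed to 80% of the control, the I-P amplitude is scaled by
    0.6 (amplitudes renormalized to sum to one) and a positive K-band of
    relative amplitude 0.05 is injected. These are tuning constants chosen
    to qualitatively reproduce the drought stress signature (FM decline,
    I-P loss, positive delta-K band), not measured values.
    """
    base = base or TransientSpec()
    amps = np.array([base.amp_oj, base.amp_ji, base.amp_ip * 0.6])
    amps = amps / amps.sum()
    return replace(
        base,
        fm=base.f0 + (base.fm - base.f0) * 0.8,
        amp_oj=float(amps[0]),
        amp_ji=float(amps[1]),
        amp_ip=float(amps[2]),
        k_band_amp=0.05,
    )


def _log_grid(spec: TransientSpec) -> np.ndarray:
    """Log-spaced grid containing the landmark times exactly."""
    grid = np.geomspace(spec.t_min, spec.t_max, spec.n_points)
    log_grid = np.log(grid)
    used: set[int] = set()
    for t_star in sorted(LANDMARK_TIMES.values()):
        order = np.argsort(np.abs(log_grid - math.log(t_star)))
        idx = next(int(i) for i in order if int(i) not in used)
        grid[idx] = t_star
        used.add(idx)
    grid.sort()
    if np.any(np.diff(grid) <= 0):  # pragma: no cover - guarded by n_points>=16
        raise ValidationError("grid construction produced duplicate times")
    return grid


def ojip_model(spec: TransientSpec, t: np.ndarray | float) -> np.ndarray | float:
    """Noise-free model fluorescence at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    fv = spec.fm - spec.f0
    rise = (
        spec.amp_oj * -np.expm1(-t / spec.tau_oj)
        + spec.amp_ji * -np.expm1(-t / spec.tau_ji)
        + spec.amp_ip * -np.expm1(-t / spec.tau_ip)
    )
    bump = spec.k_band_amp * np.exp(
        -((np.log(t) - math.log(K_BAND_TIME)) ** 2) / (2 * K_BAND_SIGMA**2)
    )
    return spec.f0 + fv * (rise + bump)


def simulate_ojip_transient(
    spec: TransientSpec, label: str = "synthetic"
) -> tuple[FluorescenceTransient, SimTruth]:
    """Simulate one OJIP transient on a 120-point log grid.

    Returns the (possibly noisy) trace and a :class:`SimTruth` recording the
    analytic landmark values F0 (50 us), F300, FJ (2 ms), FI (30 ms), the
    noise-free trace maximum FM, and the implied phi_P0 = 1 - F0/FM.
    """
    spec.validate()
    t = _log_grid(spec)
    clean = np.asarray(ojip_model(spec, t), dtype=float)
    rng = np.random.default_rng(spec.seed)
    noisy = clean * (1.0 + rng.normal(0.0, spec.noise_sd, size=clean.shape)) \
        if spec.noise_sd > 0 else clean.copy()
    noisy = np.maximum(noisy, 1e-9)

    f0 = float(ojip_model(spec, LANDMARK_TIMES["O"]))
    f300 = float(ojip_model(spec, LANDMARK_TIMES["K"]))
    fj = float(ojip_model(spec, LANDMARK_TIMES["J"]))
    fi = float(ojip_model(spec, LANDMARK_TIMES["I"]))
    fm = float(clean.max())
    truth = SimTruth(
        generator="simulate_ojip_transient",
        params={
            "F0": f0, "F300": f300, "FJ": fj, "FI": fi, "FM": fm,
            "phi_p0": 1.0 - f0 / fm,
            "k_band_amp": spec.k_band_amp,
            "spec": spec,
        },
        seed=spec.seed,
    )
    return FluorescenceTransient(time=t, fluorescence=noisy, label=label), truth


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a sample -> group design.

    ``values`` holds non-negative integer counts in ``rnaseq`` mode or log2
    intensities in ``microarray`` mode.
    """

    values: pd.DataFrame
    design: pd.Series
    mode: str = "rnaseq"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        self.design = pd.Series(self.design)
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples without group assignment: {missing}")
        if self.mode not in ("rnaseq", "microarray"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == group]


def simulate_expression_matrix(
    n_genes: int,
    groups: Mapping[str, int],
    deg_fraction: float = 0.05,
    effect_log2fc: float = 4.0,
    dispersion: float = 0.05,
    lib_sizes: Sequence[float] | None = None,
    seed: int = 0,
    mean_shape: float = 2.0,
    mean_scale: float = 250.0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate an RNA-seq-like negative-binomial count matrix.

    Baseline per-gene means are gamma distributed (shape 2, scale 250, plus
    a floor of 5 so no gene is entirely unobservable); a ``deg_fraction`` of
    genes is planted with a symmetric up/down multiplicative effect of
    ``2**effect_log2fc`` in the second (treated) group. Counts are drawn
    NB(mean mu, variance mu + dispersion * mu^2); ``dispersion == 0`` gives
    Poisson counts.
    """
    if not 0 <= deg_fraction <= 1:
        raise ValidationError("deg_fraction must be in [0, 1]")
    if len(groups) != 2:
        raise ValidationError("exactly two groups are required")
    if any(n < 2 for n in groups.values()):
        raise ValidationError("need >= 2 replicates per group (dispersion unidentifiable)")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:06d}" for i in range(n_genes)]
    (ctrl, n_ctrl), (trt, n_trt) = list(groups.items())
    samples = [f"{ctrl}_{r+1}" for r in range(n_ctrl)] + [
        f"{trt}_{r+1}" for r in range(n_trt)
    ]
    design = pd.Series([ctrl] * n_ctrl + [trt] * n_trt, index=samples)
    if lib_sizes is None:
        lib = np.ones(len(samples))
    else:
        lib = np.asarray(lib_sizes, dtype=float)
        if lib.shape != (len(samples),) or np.any(lib <= 0):
            raise ValidationError("lib_sizes must be positive, one per sample")

    base = rng.gamma(mean_shape, mean_scale, size=n_genes) + 5.0
    n_deg = int(round(deg_fraction * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_deg)
    effect = np.zeros(n_genes)
    effect[deg_idx] = signs * effect_log2fc

    mu = base[:, None] * lib[None, :]
    trt_cols = np.array([design[s] == trt for s in samples])
    mu[:, trt_cols] *= (2.0 ** effect)[:, None]

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    values = pd.DataFrame(counts, index=gene_ids, columns=samples)
    truth = SimTruth(
        generator="simulate_expression_matrix",
        params={
            "deg_genes": {gene_ids[i]: float(e) for i, e in
                          zip(deg_idx, signs * effect_log2fc)},
            "contrast": (ctrl, trt),
            "dispersion": dispersion,
            "base_means": dict(zip(gene_ids, base)),
        },
        seed=seed,
    )
    return ExpressionMatrix(values=values, design=design, mode="rnaseq"), truth


def simulate_promoter_set(
    n_seqs: int,
    length: int = 1500,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    planted: Sequence[tuple] = (),
    seed: int = 0,
    seq_ids: Sequence[str] | None = None,
) -> tuple[list[SeqRecord], SimTruth]:
    """Simulate promoter sequences with optionally planted motif sites.

    ``planted`` is a list of ``(matrix, seq_index, offset, strand)`` where
    ``matrix`` is an (L, 4) array of per-position base probabilities over
    ACGT. The planted site is drawn column-wise from the matrix; on the
    ``-`` strand its reverse complement is written into the sequence, so the
    site occupies positions ``offset .. offset+L`` of the plus strand.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValidationError("background must be 4 positive frequencies summing to 1")
    rng = np.random.default_rng(seed)
    seqs = [rng.choice(4, size=length, p=bg) for _ in range(n_seqs)]
    sites = []
    for matrix, idx, offset, strand in planted:
        matrix = np.asarray(matrix, dtype=float)
        if not 0 <= idx < n_seqs:
            raise ValidationError(f"sequence index {idx} out of range")
        if strand not in "+-":
            raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
        w = matrix.shape[0]
        if offset < 0 or offset + w > length:
            raise ValidationError(
                f"offset {offset} puts a {w}-bp motif outside a {length}-bp sequence"
            )
        drawn = "".join(_BASES[rng.choice(4, p=matrix[i] / matrix[i].sum())]
                        for i in range(w))
        site = drawn if strand == "+" else drawn.translate(_COMPLEMENT)[::-1]
        seqs[idx][offset:offset + w] = [_BASES.index(b) for b in site]
        sites.append({"seq_index": idx, "offset": offset, "strand": strand,
                      "site": drawn})
    ids = list(seq_ids) if seq_ids is not None else [
        f"promoter_{i:04d}" for i in range(n_seqs)
    ]
    if len(ids) != n_seqs:
        raise ValidationError("seq_ids length must equal n_seqs")
    records = [
        SeqRecord(Seq("".join(_BASES[b] for b in s)), id=sid, description="")
        for s, sid in zip(seqs, ids)
    ]
    truth = SimTruth(
        generator="simulate_promoter_set",
        params={"planted": sites, "background": tuple(bg)},
        seed=seed,
    )
    return records, truth


def simulate_qpcr_plate(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_fc: Mapping[str, float],
    efficiency: Mapping[str, float] | float = 2.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a qPCR Ct table from known fold changes.

    The first condition is the control. For each other condition,
    ``Ct_treated = Ct_control - log_E(FC) + noise`` so that the fold-change
    formula ``FC = E^-(Ct_treated - Ct_control)`` recovers ``true_fc``
    exactly in the noise-free case.
    """
    if len(conditions) < 2:
        raise ValidationError("need a control and at least one treated condition")
    rng = np.random.default_rng(seed)
    rows = []
    control = conditions[0]
    for gene in genes:
        e = efficiency[gene] if isinstance(efficiency, Mapping) else efficiency
        if not 1.0 < e <= 2.0:
            raise ValidationError(f"efficiency for {gene} must be in (1, 2], got {e}")
        fc = true_fc.get(gene, 1.0)
        if fc <= 0:
            raise ValidationError(f"fold change for {gene} must be > 0, got {fc}")
        ct_control = rng.uniform(18.0, 28.0)
        rows.append({"gene": gene, "condition": control,
                     "mean_ct": ct_control, "efficiency": e})
        for cond in conditions[1:]:
            ct = ct_control - math.log(fc, e) + rng.normal(0.0, ct_noise_sd)
            rows.append({"gene": gene, "condition": cond,
                         "mean_ct": ct, "efficiency": e})
    table = pd.DataFrame(rows)
    if (table["mean_ct"] <= 0).any():
        raise ValidationError("simulated Ct values must be positive; "
                              "fold changes too extreme for the Ct range")
    truth = SimTruth(
        generator="simulate_qpcr_plate",
        params={"true_fc": dict(true_fc), "control": control},
        seed=seed,
    )
    return table, truth
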