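"""Synthetic data with planted ground truth.

Three generators cover the three data types the pipeline consumes:

* ``synth_cells`` / ``synth_counts`` — Smart-seq2-scale negative-binomial
  counts for lineage-labelled epidermal cells positioned on a latent
  differentiation coordinate z in [0, 1] (0 = Lrig1-high stem-like state,
  1 = Gata6-high differentiated state). Wounded lineage-positive cells drift
  back toward z = 0 (dedifferentiation) at a configurable rate.
* ``synth_force_curve`` — AFM force-distance approach curves of known Young's
  modulus obtained by inverting the spherical-indenter Hertz relation.
* ``synth_fiber_mask`` — binary fiber masks of known total length.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy import sparse

from .sc_core import CountMatrix, CellAnnotations, LINEAGES, TIMEPOINTS

__all__ = [
    "SynthConfig",
    "LatentCellState",
    "MarkerProgram",
    "ForceCurveData",
    "default_config",
    "synth_cells",
    "synth_counts",
    "synth_force_curve",
    "synth_fiber_mask",
    "hertz_force",
    "write_counts_mtx",
    "write_force_curve",
    "write_mask_png",
]

HERTZ_NU_DEFAULT = 0.5


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class MarkerProgram:
    """A compartment marker program: which genes, what trend shape along z,
    and the effect size (natural-log fold units at full activation)."""

    genes: tuple[int, ...]
    shape: str  # "up" | "down" | "transient"
    effect: float
    baseline: float | None = None  # fixed log-baseline (else drawn per gene)

    def activation(self, z: np.ndarray) -> np.ndarray:
        if self.shape == "up":
            return z
        if self.shape == "down":
            return 1.0 - z
        if self.shape == "transient":
            return np.exp(-((z - 0.5) ** 2) / (2 * 0.15 ** 2))
        raise ValueError(f"unknown program shape {self.shape!r}")


@dataclass
class SynthConfig:
    """Study-design parameters of the count generator.

    ``n_cells_per_group`` is keyed by (lineage, timepoint, batch). The default
    configuration mirrors the study design: 684 cells over two lineages, four
    timepoints (days 0/6/9/11) and two batches per timepoint.
    """

    n_cells_per_group: dict[tuple[str, int, str], int]
    n_genes: int = 800
    marker_programs: dict[str, MarkerProgram] = field(default_factory=dict)
    reversal_strength: float = 0.4
    dispersion: float = 2.0  # NB inverse-dispersion (size); var = mu + mu^2/size
    library_size_lognormal: tuple[float, float] = (np.log(30.0), 0.3)
    batch_shift_sd: float = 0.3
    baseline_sd: float = 0.5
    wound_genes: tuple[int, ...] = ()
    wound_effect: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells_per_group:
            raise ValueError("empty group table")
        for (lin, tp, _b), cnt in self.n_cells_per_group.items():
            if lin not in LINEAGES:
                raise ValueError(f"unknown lineage {lin!r}")
            if int(tp) not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {tp!r}")
            if cnt < 0:
                raise ValueError("negative group count")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.reversal_strength < 0:
            raise ValueError("reversal_strength must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")
        used: set[int] = set()
        n_marker = 0
        for prog in self.marker_programs.values():
            gs = set(prog.genes)
            if len(gs) != len(prog.genes):
                raise ValueError("marker program contains duplicate gene indices")
            if gs & used:
                raise ValueError("marker programs overlap")
            if any(g < 0 or g >= self.n_genes for g in gs):
                raise ValueError("marker gene index out of range")
            used |= gs
            n_marker += len(gs)
        if n_marker + len(self.wound_genes) > self.n_genes:
            raise ValueError("n_genes smaller than total marker genes")

    @property
    def named_genes(self) -> dict[str, int]:
        """Indices of the individually named marker genes."""
        named = {}
        for name in ("Lrig1", "Gata6", "Krt6a", "Krt6b"):
            if name in self.marker_programs:
                named[name] = self.marker_programs[name].genes[0]
        return named


@dataclass
class LatentCellState:
    z: float
    lineage: str
    timepoint: int
    batch: str


def default_config(seed: int = 0) -> SynthConfig:
    """The default study-like design: 684 cells, 800 genes, five compartment
    programs plus named Lrig1/Gata6/wound markers."""
    groups: dict[tuple[str, int, str], int] = {}
    per_batch = {
        ("pos", 0): 30, ("pos", 6): 45, ("pos", 9): 52, ("pos", 11): 52,
        ("neg", 0): 65, ("neg", 6): 33, ("neg", 9): 33, ("neg", 11): 32,
    }
    for (lin, tp), cnt in per_batch.items():
        for batch in ("b1", "b2"):
            groups[(lin, tp, batch)] = cnt

    # gene layout: 0 Lrig1, 1 Gata6, 2-3 Krt6a/b (wound), then block programs
    programs = {
        # switch-like markers: near-zero counts when off, high when on
        "Lrig1": MarkerProgram(genes=(0,), shape="down", effect=6.0, baseline=-4.6),
        "Gata6": MarkerProgram(genes=(1,), shape="up", effect=6.0, baseline=-4.6),
        "uHF": MarkerProgram(genes=tuple(range(10, 50)), shape="up", effect=5.0, baseline=-3.5),
        "SD": MarkerProgram(genes=tuple(range(50, 80)), shape="up", effect=5.0, baseline=-3.5),
        "IFE": MarkerProgram(genes=tuple(range(80, 120)), shape="down", effect=5.0, baseline=-3.5),
        "OB": MarkerProgram(genes=tuple(range(120, 145)), shape="down", effect=5.0, baseline=-3.5),
        "SG": MarkerProgram(genes=tuple(range(145, 170)), shape="transient", effect=5.0, baseline=-3.5),
    }
    return SynthConfig(
        n_cells_per_group=groups,
        n_genes=800,
        marker_programs=programs,
        wound_genes=(2, 3, 170, 171),
        wound_effect=1.2,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Latent states and counts
# ---------------------------------------------------------------------------

def synth_cells(config: SynthConfig) -> list[LatentCellState]:
    """Draw one latent state per configured cell.

    Unwounded lineage-positive cells sit near z = 1 (differentiated);
    lineage-negative cells are mostly basal (near 0) with a differentiated
    tail; wounded lineage-positive cells shift toward 0 with timepoint at rate
    ``reversal_strength`` (active after a 6-day lag, so day-6 wounds resemble
    day 0 while day-9/11 wounds are strongly shifted).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    states: list[LatentCellState] = []
    for (lin, tp, batch), cnt in sorted(config.n_cells_per_group.items()):
        tp = int(tp)
        if cnt == 0:
            continue
        if lin == "pos":
            z = 0.8 + 0.2 * rng.beta(2.0, 2.0, size=cnt)
            if tp > 0:
                z = z * np.exp(-config.reversal_strength * max(0, tp - 6))
        else:
            basal = rng.beta(1.2, 4.0, size=cnt)
            diff = rng.beta(6.0, 1.5, size=cnt)
            pick = rng.random(cnt) < 0.75
            z = np.where(pick, basal, diff)
        for zi in z:
            states.append(LatentCellState(z=float(np.clip(zi, 0.0, 1.0)),
                                          lineage=lin, timepoint=tp, batch=batch))
    if not states:
        raise ValueError("group table produced no cells")
    return states


def synth_counts(
    states: list[LatentCellState], config: SynthConfig
) -> tuple[CountMatrix, CellAnnotations, dict]:
    """Negative-binomial counts for the given latent states.

    Mean model: mu_gc = lib_c * exp(baseline_g + effect_g * f_g(z_c) +
    wound_g * [timepoint_c > 0] + batchshift_gb). Returns the counts, the cell
    metadata and a ground-truth dict (z per cell, program membership).
    """
    if not states:
        raise ValueError("no latent states supplied")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_genes = config.n_genes
    n_cells = len(states)
    z = np.array([s.z for s in states])
    tp = np.array([s.timepoint for s in states])
    batches = [s.batch for s in states]
    batch_levels = sorted(set(batches))
    batch_idx = np.array([batch_levels.index(b) for b in batches])

    baseline = rng.normal(0.0, config.baseline_sd, size=n_genes)
    for prog in config.marker_programs.values():
        if prog.baseline is not None:
            baseline[list(prog.genes)] = prog.baseline
    log_mu = np.tile(baseline[:, None], (1, n_cells))
    for prog in config.marker_programs.values():
        act = prog.activation(z)
        for g in prog.genes:
            log_mu[g] += prog.effect * act
    for g in config.wound_genes:
        log_mu[g] += config.wound_effect * (tp > 0)
    if config.batch_shift_sd > 0 and len(batch_levels) > 1:
        shifts = rng.normal(0.0, config.batch_shift_sd, size=(n_genes, len(batch_levels)))
        log_mu += shifts[:, batch_idx]
    lib = rng.lognormal(config.library_size_lognormal[0],
                        config.library_size_lognormal[1], size=n_cells)
    mu = lib[None, :] * np.exp(log_mu)
    size = config.dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(np.int64)

    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    for name, gi in config.named_genes.items():
        gene_ids[gi] = name
    for prog_name, prog in config.marker_programs.items():
        if prog_name in ("Lrig1", "Gata6"):
            continue
        for j, g in enumerate(prog.genes):
            gene_ids[g] = f"{prog_name}_{j:02d}"
    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "lineage": [s.lineage for s in states],
            "timepoint": tp,
            "batch": batches,
        }
    )
    truth = {
        "z": z.tolist(),
        "programs": {
            name: [gene_ids[g] for g in prog.genes]
            for name, prog in config.marker_programs.items()
        },
        "program_shapes": {name: p.shape for name, p in config.marker_programs.items()},
        "program_effects": {name: p.effect for name, p in config.marker_programs.items()},
        "wound_genes": [gene_ids[g] for g in config.wound_genes],
    }
    return (
        CountMatrix(values=counts, gene_ids=gene_ids, cell_ids=cell_ids),
        CellAnnotations(meta),
        truth,
    )


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

def hertz_force(E: float, R_tip: float, delta, nu: float = HERTZ_NU_DEFAULT) -> np.ndarray:
    """Spherical-indenter Hertz force F = 4 E sqrt(R) delta^{3/2} / (3 (1 - nu^2))."""
    delta = np.asarray(delta, dtype=float)
    return 4.0 * E * np.sqrt(R_tip) / (3.0 * (1.0 - nu ** 2)) * np.clip(delta, 0, None) ** 1.5


@dataclass
class ForceCurveData:
    """A synthetic approach curve plus its generating truth."""

    z: np.ndarray  # piezo extension, m
    deflection: np.ndarray  # cantilever deflection, m
    k_spring: float
    sensitivity: float
    R_tip: float
    nu: float
    E_true: float
    z0_true: float


def synth_force_curve(
    E_true: float,
    R_tip: float = 2.5e-6,
    k_spring: float = 0.25,
    z0: float = 2.0e-6,
    noise_sd: float = 0.0,
    z_max: float = 5.0e-6,
    n_points: int = 400,
    nu: float = HERTZ_NU_DEFAULT,
    sensitivity: float = 50e-9,
    seed: int = 0,
) -> ForceCurveData:
    """Generate an approach force curve of known modulus.

    For piezo positions past the contact point the indentation solves
    delta + F(delta)/k = z - z0 self-consistently (the cantilever bends by
    F/k, reducing the indentation). Gaussian force noise of ``noise_sd``
    newtons is added to the deflection channel.
    """
    if E_true <= 0 or R_tip <= 0 or k_spring <= 0:
        raise ValueError("E_true, R_tip and k_spring must be positive")
    if not 0 <= nu <= 0.5:
        raise ValueError("nu must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, z_max, n_points)
    A = 4.0 * E_true * np.sqrt(R_tip) / (3.0 * (1.0 - nu ** 2))
    delta = np.zeros_like(z)
    past = z > z0
    s = z[past] - z0
    d = np.minimum(s, (k_spring * s / A) ** (2.0 / 3.0))  # init below root
    for _ in range(100):
        f = d + A * d ** 1.5 / k_spring - s
        fp = 1.0 + 1.5 * A * np.sqrt(d) / k_spring
        step = f / fp
        d = np.clip(d - step, 0.0, s)
        if np.max(np.abs(step)) < 1e-18:
            break
    delta[past] = d
    force = A * delta ** 1.5
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    deflection = force / k_spring
    return ForceCurveData(
        z=z, deflection=deflection, k_spring=k_spring, sensitivity=sensitivity,
        R_tip=R_tip, nu=nu, E_true=E_true, z0_true=z0,
    )


# ---------------------------------------------------------------------------
# Fiber masks
# ---------------------------------------------------------------------------

def synth_fiber_mask(
    segments: list[tuple[tuple[int, int], tuple[int, int]]],
    image_shape: tuple[int, int],
    px_size: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Rasterize straight 1-px-wide segments into a binary mask.

    Returns (mask, ground-truth total length in µm), the truth being the sum
    of Euclidean endpoint distances times the pixel size.
    """
    from skimage.draw import line as sk_line

    mask = np.zeros(image_shape, dtype=np.uint8)
    total = 0.0
    for (r0, c0), (r1, c1) in segments:
        for r, c in ((r0, c0), (r1, c1)):
            if not (0 <= r < image_shape[0] and 0 <= c < image_shape[1]):
                raise ValueError(f"segment endpoint ({r}, {c}) outside image")
        rr, cc = sk_line(r0, c0, r1, c1)
        mask[rr, cc] = 1
        total += float(np.hypot(r1 - r0, c1 - c0)) * px_size
    return mask, total


# ---------------------------------------------------------------------------
# Writers (plain-text external formats)
# ---------------------------------------------------------------------------

def synth_regulons(
    config: SynthConfig,
    gene_ids: list[str],
    n_decoys: int = 10,
    targets_per_decoy: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """TRRUST-dialect edge table with one planted TF per marker program
    (targeting that program's genes) plus decoy TFs with random targets."""
    rng = np.random.default_rng(seed)
    rows = []
    for name, prog in config.marker_programs.items():
        if len(prog.genes) < 3:
            continue
        tf = f"TF_{name}"
        for g in prog.genes:
            rows.append((tf, gene_ids[g], "Activation", "planted"))
    for d in range(n_decoys):
        tf = f"TF_decoy{d:02d}"
        targets = rng.choice(len(gene_ids), size=targets_per_decoy, replace=False)
        for g in targets:
            rows.append((tf, gene_ids[g], "Unknown", "decoy"))
    return pd.DataFrame(rows, columns=["tf", "target", "mode", "references"])


def write_regulons_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", header=False, index=False)


def synth_afm_dataset(
    outdir,
    shape: tuple[int, int] = (24, 24),
    E_left: float = 3e3,
    E_right: float = 12e3,
    noise_sd: float = 0.05e-9,
    seed: int = 0,
) -> "pd.DataFrame":
    """A synthetic stiffness-map dataset: per-curve TSVs on a grid whose left
    half is soft and right half stiff, plus a manifest CSV (curve, row, col).
    Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(shape[0] * shape[1]) % (2 ** 31)
    i = 0
    for r in range(shape[0]):
        for c in range(shape[1]):
            E = E_left if c < shape[1] // 2 else E_right
            curve = synth_force_curve(E, noise_sd=noise_sd, seed=int(seeds[i]))
            i += 1
            fname = f"curve_r{r:02d}_c{c:02d}.tsv"
            write_force_curve(curve, outdir / fname)
            rows.append({"curve": fname, "row": r, "col": c, "E_true": E})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def synth_fiber_scene(
    image_shape: tuple[int, int] = (128, 128),
    n_fibers: int = 25,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Random straight fibers across an image; returns (mask, true length µm)."""
    rng = np.random.default_rng(seed)
    segs = []
    h, w = image_shape
    for _ in range(n_fibers):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.2, 0.6) * min(h, w)
        r1 = int(np.clip(r0 + length * np.sin(ang), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(ang), 0, w - 1))
        segs.append(((int(r0), int(c0)), (r1, c1)))
    return synth_fiber_mask(segs, image_shape)


def write_counts_mtx(counts: CountMatrix, meta: CellAnnotations, outdir,
                     truth: dict | None = None) -> None:
    """Write MTX (genes x cells, 1-based triplets) + genes.tsv + barcodes.tsv
    + cell_metadata.tsv (+ ground_truth.json when provided)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(counts.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    meta.table.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    if truth is not None:
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def write_force_curve(curve: ForceCurveData, path) -> None:
    """Two-column TSV (z in m, deflection in volts) with '#'-prefixed metadata."""
    path = Path(path)
    volts = curve.deflection / curve.sensitivity
    with open(path, "w") as fh:
        fh.write(f"# k_spring\t{curve.k_spring!r}\n")
        fh.write(f"# sensitivity\t{curve.sensitivity!r}\n")
        fh.write(f"# R_tip\t{curve.R_tip!r}\n")
        fh.write(f"# nu\t{curve.nu!r}\n")
        for zi, vi in zip(curve.z, volts):
            fh.write(f"{zi:.12e}\t{vi:.12e}\n")


def write_mask_png(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)
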