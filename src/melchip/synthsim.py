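"""Forward simulation of the clamped-PCR hybridization assay.

The wet assay enriches mutant template with an LNA PCR clamp (a non-extendable
oligomer that binds the wild-type allele and blocks its amplification), labels
the product fluorescently, and hybridizes it to allele-specific probes in
hydrogel spots.  This module models that chain well enough to ground-truth the
image-analysis and calling stages:

* clamp PCR — capped geometric growth with allele-specific per-cycle
  efficiencies (mutant ``eff_mut`` ≫ clamped wild type ``eff_wt_clamped``);
* hybridization — probe signal proportional to product amount through a
  ``gain``, with a small cross-hybridization weight between alleles of the
  same locus group, on top of a uniform chip background;
* acquisition — spots rendered as soft disks into a 16-bit grayscale image
  with multiplicative spot noise and additive pixel noise.

Default parameters are calibrated so the simulated dilution series reproduces
the assay's measured limit of detection: 0.25% mutant fraction fails the
calling rule while 0.5% passes it in every replicate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .panel import (ChipLayout, EXCLUSIVE_GENES, LayoutGeometry, MutationPanel,
                    PanelEntry, PanelError, build_layout, load_default_panel)

#: dilution fractions of the sensitivity experiment (% mutant DNA / 100)
DEFAULT_FRACTIONS = (0.0, 0.0025, 0.005, 0.01, 0.05, 0.10, 0.50, 1.0)
DEFAULT_REPLICATES = 3

MARKER_INTENSITY = 30000.0


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated sample."""

    genotype: tuple[PanelEntry, ...]  # empty tuple = wild type
    mutant_fraction: float
    dna_input: float = 1e4  # template copies entering the clamp PCR

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutant_fraction <= 1.0:
            raise ValueError("mutant_fraction must lie in [0, 1]")
        if (self.mutant_fraction == 0.0) != (len(self.genotype) == 0):
            raise ValueError("mutant_fraction is 0 iff the genotype is empty")


@dataclass(frozen=True)
class ClampParams:
    cycles: int = 35
    eff_mut: float = 0.9
    eff_wt_clamped: float = 0.2
    saturation_cap: float = 1e12

    def __post_init__(self) -> None:
        if not (0.0 < self.eff_mut <= 1.0) or not (0.0 <= self.eff_wt_clamped < 1.0):
            raise ValueError("efficiencies out of range")
        if self.eff_wt_clamped >= self.eff_mut:
            raise ValueError("clamped WT efficiency must be below mutant efficiency")
        if self.saturation_cap <= 0:
            raise ValueError("saturation cap must be positive")


@dataclass(frozen=True)
class HybParams:
    gain: float = 2.6e-9         # signal units per product copy
    crosshyb: float = 0.05       # off-diagonal weight within a locus group
    background_mean: float = 600.0  # measured background intensity (incl. dark current)
    dark_current: float = 100.0
    spot_cv: float = 0.10        # multiplicative log-normal CV on spot signal

    def __post_init__(self) -> None:
        if not 0.0 <= self.crosshyb < 1.0:
            raise ValueError("cross-hybridization weight must be in [0, 1)")
        if not self.background_mean > self.dark_current >= 0.0:
            raise ValueError("need background_mean > dark_current >= 0")


@dataclass(frozen=True)
class ImageParams:
    bit_depth: int = 16
    edge_softness: float = 1.0   # px over which the disk edge rolls off
    pixel_noise_sd: float = 20.0

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


# ---------------------------------------------------------------------------
# Clamp PCR
# ---------------------------------------------------------------------------


def simulate_clamp_pcr(truth: SampleTruth, p: ClampParams,
                       panel: MutationPanel) -> dict[str, dict[str, float]]:
    """Per-group product copies after the clamped multiplex PCR.

    Every locus group amplifies in its own multiplex reaction.  Mutant
    template (fraction ``f`` of ``dna_input``) grows at ``1 + eff_mut`` per
    cycle; clamped wild-type template at ``1 + eff_wt_clamped``; both are
    capped at ``saturation_cap``.  Deterministic.

    Returns ``{group_id: {allele_probe_id_or_'wt': copies}}``.
    """
    f = truth.mutant_fraction
    n0 = truth.dna_input
    mut_growth = (1.0 + p.eff_mut) ** p.cycles
    wt_growth = (1.0 + p.eff_wt_clamped) ** p.cycles
    wt_amount = min(p.saturation_cap, (1.0 - f) * n0 * wt_growth)
    by_group: dict[str, dict[str, float]] = {}
    for grp in panel.groups:
        products = {"wt": wt_amount}
        for e in grp.entries:
            if e in truth.genotype:
                products[e.probe_id] = min(p.saturation_cap, f * n0 * mut_growth)
        by_group[grp.group_id] = products
    return by_group


# ---------------------------------------------------------------------------
# Hybridization to spots
# ---------------------------------------------------------------------------


def _probe_hyb(products: dict[str, float], probe_id: str, is_wt: bool,
               crosshyb: float) -> float:
    """Hybridized product on one probe: matched allele weight 1, mismatched
    alleles of the same group weight ``crosshyb``."""
    total = 0.0
    for allele, amount in products.items():
        matched = (allele == "wt") if is_wt else (allele == probe_id)
        total += amount * (1.0 if matched else crosshyb)
    return total


def simulate_spot_truth(products: dict[str, dict[str, float]], layout: ChipLayout,
                        h: HybParams, seed: int | None = None,
                        noise: bool = True) -> tuple[dict[int, float], dict[int, float]]:
    """Assign an intensity to every occupied spot.

    Returns ``(noiseless, noisy)`` maps of spot index to intensity in measured
    camera units (background included).  Duplicated spots of one probe receive
    independent multiplicative noise draws; marker spots get a fixed bright
    value.  ``seed`` is required whenever noise is requested, so every noisy
    realization is reproducible.
    """
    if noise and seed is None:
        raise ValueError("a seed is required for a noisy realization")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(h.spot_cv ** 2))
    noiseless: dict[int, float] = {}
    noisy: dict[int, float] = {}
    for idx in layout.occupied:
        role = layout.spot_map[idx]
        if role.kind == "marker":
            noiseless[idx] = MARKER_INTENSITY
            noisy[idx] = MARKER_INTENSITY
            continue
        grp_products = products.get(role.group_id, {"wt": 0.0})
        hyb = _probe_hyb(grp_products, role.probe_id, role.kind == "wt", h.crosshyb)
        signal = h.gain * hyb
        noiseless[idx] = h.background_mean + signal
        if noise:
            factor = float(np.exp(rng.normal(-sigma ** 2 / 2.0, sigma)))
            noisy[idx] = h.background_mean + signal * factor
        else:
            noisy[idx] = noiseless[idx]
    return noiseless, noisy


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def spot_centers(layout: ChipLayout) -> dict[int, tuple[float, float]]:
    """Nominal (row_px, col_px) centre of every occupied spot."""
    g = layout.geometry
    out = {}
    for idx in layout.occupied:
        r, c = layout.grid_position(idx)
        out[idx] = (g.margin + r * g.pitch, g.margin + c * g.pitch)
    return out


def image_shape(layout: ChipLayout) -> tuple[int, int]:
    g = layout.geometry
    h = int(round(2 * g.margin + (g.rows - 1) * g.pitch)) + 1
    w = int(round(2 * g.margin + (g.cols - 1) * g.pitch)) + 1
    return h, w


def render_chip_image(spot_values: dict[int, float], layout: ChipLayout,
                      ip: ImageParams | None = None, h: HybParams | None = None,
                      seed: int | None = None, pixel_noise: bool = True) -> np.ndarray:
    """Render assigned spot intensities into a 16-bit grayscale chip image.

    Spots are anti-aliased disks whose interior mean equals the assigned
    intensity before pixel noise; off-spot pixels sit at the background mean.
    Values beyond the bit depth are clipped (with a warning).
    """
    ip = ip or ImageParams()
    h = h or HybParams()
    if pixel_noise and seed is None:
        raise ValueError("a seed is required for pixel noise")
    shape = image_shape(layout)
    img = np.full(shape, h.background_mean, dtype=np.float64)
    g = layout.geometry
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    centers = spot_centers(layout)
    for idx, value in spot_values.items():
        cy, cx = centers[idx]
        d = np.hypot(yy - cy, xx - cx)
        w = np.clip((g.radius + ip.edge_softness / 2.0 - d) / ip.edge_softness, 0.0, 1.0)
        img += w * (value - h.background_mean)
    if pixel_noise:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, ip.pixel_noise_sd, size=shape)
    if img.max() > ip.max_value:
        warnings.warn("rendered intensity exceeds bit depth; clipping", stacklevel=2)
    return np.clip(np.rint(img), 0, ip.max_value).astype(np.uint16)


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulatedChip:
    image: np.ndarray = field(hash=False)
    truth: SampleTruth
    manifest: dict = field(hash=False)


def simulate_chip(truth: SampleTruth, layout: ChipLayout, panel: MutationPanel,
                  clamp: ClampParams, hyb: HybParams, ip: ImageParams,
                  seed: int, sample_id: str = "sample") -> SimulatedChip:
    """Full forward model for one chip: clamp PCR → hybridization → image."""
    products = simulate_clamp_pcr(truth, clamp, panel)
    _, noisy = simulate_spot_truth(products, layout, hyb, seed=seed)
    image = render_chip_image(noisy, layout, ip, hyb, seed=seed + 1)
    manifest = {
        "sample_id": sample_id,
        "genotype": [e.probe_id for e in truth.genotype],
        "mutant_fraction": truth.mutant_fraction,
        "dna_input": truth.dna_input,
        "seed": seed,
        "dark_current": hyb.dark_current,
        "background_mean": hyb.background_mean,
    }
    return SimulatedChip(image, truth, manifest)


def generate_dilution_series(mutation: PanelEntry,
                             fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
                             replicates: int = DEFAULT_REPLICATES,
                             seed: int = 0,
                             panel: MutationPanel | None = None,
                             layout: ChipLayout | None = None,
                             clamp: ClampParams | None = None,
                             hyb: HybParams | None = None,
                             ip: ImageParams | None = None) -> list[SimulatedChip]:
    """Simulate the sensitivity experiment: mutant DNA serially diluted in
    wild-type DNA, each fraction in replicate.

    Defaults are the eight measured fractions (0, 0.25, 0.5, 1, 5, 10, 50,
    100%) in triplicate.  Per-replicate seeds derive deterministically from
    the master seed.
    """
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    panel = panel or load_default_panel()
    layout = layout or build_layout(panel)
    clamp = clamp or ClampParams()
    hyb = hyb or HybParams()
    ip = ip or ImageParams()
    chips = []
    # derive well-separated child seeds from the master seed
    children = np.random.SeedSequence(seed).generate_state(2 * len(fractions) * replicates)
    k = 0
    for f in fractions:
        genotype = (mutation,) if f > 0 else ()
        for rep in range(replicates):
            child = int(children[k] % (2 ** 31 - 1))
            k += 2
            truth = SampleTruth(genotype, f)
            chip = simulate_chip(
                truth, layout, panel, clamp, hyb, ip, seed=child,
                sample_id=f"dilution_f{f:g}_rep{rep + 1}",
            )
            chip.manifest["fraction"] = f
            chip.manifest["replicate"] = rep + 1
            chip.manifest["master_seed"] = seed
            chips.append(chip)
    return chips


def write_chip(chip: SimulatedChip, image_path) -> None:
    """Write a chip image as 16-bit grayscale TIFF plus a JSON truth sidecar."""
    import tifffile

    tifffile.imwrite(str(image_path), chip.image)
    sidecar = str(image_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(chip.manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------

#: biochip per-variant cohort frequencies observed in the 253-patient study
def default_variant_freqs(panel: MutationPanel | None = None) -> dict[str, float]:
    panel = panel or load_default_panel()
    counts = {
        "BRAF:c.1799T>A": 111, "BRAF:c.1798_1799delGTinsAA": 14,
        "BRAF:c.1798_1799delGTinsAG": 3, "BRAF:c.1798G>A": 1,
        "NRAS:c.37G>C": 1, "NRAS:c.38G>A": 1, "NRAS:c.182A>G": 17,
        "NRAS:c.183A>C": 2, "NRAS:c.183A>T": 1, "NRAS:c.181C>A": 20,
        "NRAS:c.182A>T": 3,
        "KIT:c.1727T>C": 5, "KIT:c.1924A>G": 1,
        "GNAQ:c.626A>C": 2, "GNAQ:c.626A>T": 2,
        "GNA11:c.626A>T": 2,
        "MAP2K1:c.370C>T": 2,
    }
    return {pid: n / 253.0 for pid, n in counts.items()}


def generate_cohort(n: int, variant_freqs: dict[str, float] | None = None,
                    seed: int = 0, panel: MutationPanel | None = None,
                    method_dropout: float = 0.0,
                    methods: tuple[str, ...] = ("biochip",)):
    """Sample a synthetic patient cohort with known genotypes.

    Driver genes BRAF/NRAS/KIT/GNAQ/GNA11 are drawn jointly (mutually
    exclusive); MAP2K1/2 variants are allowed only on BRAF-mutant patients,
    preserving their marginal frequency.  Each requested method observes the
    genotype with an optional per-method dropout probability.  Clinical
    covariates follow the study's observed margins (sex, age, subtype).
    """
    import pandas as pd

    panel = panel or load_default_panel()
    freqs = variant_freqs if variant_freqs is not None else default_variant_freqs(panel)
    if sum(freqs.values()) > 1.0 + 1e-12:
        raise ValueError("variant frequencies sum to more than 1")
    rng = np.random.default_rng(seed)

    excl = {pid: p for pid, p in freqs.items() if pid.split(":")[0] in EXCLUSIVE_GENES}
    mapk = {pid: p for pid, p in freqs.items() if pid.split(":")[0] in ("MAP2K1", "MAP2K2")}
    p_braf = sum(p for pid, p in excl.items() if pid.startswith("BRAF"))

    excl_ids = list(excl)
    probs = np.array([excl[pid] for pid in excl_ids])
    p_wt = 1.0 - probs.sum()

    rows = []
    for i in range(n):
        u = rng.random()
        acc, chosen = 0.0, None
        for pid, p in zip(excl_ids, probs):
            acc += p
            if u < acc:
                chosen = pid
                break
        genotype = [chosen] if chosen else []
        if chosen and chosen.startswith("BRAF") and p_braf > 0:
            for pid, p in mapk.items():
                if rng.random() < p / p_braf:
                    genotype.append(pid)
        sex = rng.choice(["F", "M", None], p=[140 / 253, 97 / 253, 16 / 253])
        age = float(np.clip(rng.normal(53.7, 16.4), 1.0, 90.0))
        subtype = rng.choice(
            ["nodular", "superficial", "lentigo", "acral", None],
            p=[43 / 253, 24 / 253, 10 / 253, 1 / 253, 175 / 253],
        )
        row = {
            "sample_id": f"sim{i + 1:04d}",
            "truth": ";".join(genotype) if genotype else "WT",
            "sex": sex, "age": round(age, 1), "subtype": subtype,
        }
        for m in methods:
            observed = [pid for pid in genotype if rng.random() >= method_dropout]
            row[m] = ";".join(observed) if observed else "WT"
        rows.append(row)
    cols = ["sample_id", "truth", *methods, "sex", "age", "subtype"]
    return pd.DataFrame(rows, columns=cols)
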