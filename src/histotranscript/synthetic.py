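"""Paired synthetic histology-image / gene-expression datasets with planted truth.

The generator emulates the statistical structure the correlation analysis
assumes, not histological realism. Each tissue class has a distinctive visual
regime (cell color palette, cell size and packing density); each slide draws
continuous within-class visual latents (cell radius in px, cell density per
10^4 px^2, palette hue shift) and is rendered as randomly placed disk "cells"
on a white background. Gene expression on the log2 scale is generated from
that same latent table:

* ``direct`` genes track one visual latent linearly plus Gaussian noise,
* ``tissue_marker`` genes depend only on the class label (so any gene-feature
  correlation they show is indirect, mediated by tissue identity),
* ``null`` genes are pure noise.

Raw expression is recovered as E = 2^x - 1, which makes the pipeline's
log2(1+E) transform an exact round trip. A configurable fraction of slides
receives a duplicate (re-noised) expression sample, mirroring replicate
expression profiling of one donor block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tiler import SlideRecord


@dataclass(frozen=True)
class ClassStyle:
    """Visual regime of one synthetic tissue class."""

    name: str
    color: tuple[int, int, int]   # base RGB of the disk cells
    radius: float                 # mean cell radius, px
    density: float                # mean cells per 10^4 px^2


DEFAULT_STYLES = [
    ClassStyle("glandular", (130, 70, 150), radius=10.0, density=55.0),
    ClassStyle("stromal", (225, 130, 160), radius=9.0, density=60.0),
    ClassStyle("mucosal", (80, 100, 185), radius=13.0, density=38.0),
    ClassStyle("adipose", (170, 120, 90), radius=9.0, density=60.0),
    ClassStyle("cortical", (110, 150, 120), radius=11.0, density=45.0),
    ClassStyle("medullar", (190, 160, 100), radius=8.0, density=65.0),
]

#: within-class latent standard deviations (same units as the latents); set so
#: within-class visual variation is a substantial fraction of the between-class
#: spread — the continuous-phenotype regime the correlation analysis assumes
LATENT_SD = {"cell_radius": 1.5, "cell_density": 7.0, "hue_shift": 10.0}

#: 8-bit units of red gain / blue loss per unit of the hue latent
HUE_GAIN = 1.0

#: latents targeted by direct genes: the two whose visual footprint (cell
#: coverage) is first-order; hue stays a nuisance latent so within-class
#: color variation exists without being tied to any planted gene
DIRECT_TARGETS = ("cell_density", "cell_radius")
LATENTS = ("cell_radius", "cell_density", "hue_shift")


@dataclass(frozen=True)
class GeneSpec:
    """How one synthetic gene's log2 expression is generated."""

    gene: str
    gtype: str                          # direct | tissue_marker | null
    target: str | None = None           # latent tracked by a direct gene
    amplitude: float = 1.5              # log2 units per SD of the target latent
    intercept: float = 8.0
    sigma: float = 0.7265               # noise SD -> rho 0.9 at amplitude 1.5
    class_means: tuple[float, ...] | None = None

    @property
    def true_corr(self) -> float:
        if self.gtype != "direct":
            return float("nan")
        return self.amplitude / np.hypot(self.amplitude, self.sigma)


def sample_latents(class_idx: int, rng: np.random.Generator,
                   styles: list[ClassStyle] = DEFAULT_STYLES) -> dict[str, float]:
    st = styles[class_idx]
    return {
        "cell_radius": max(3.0, st.radius + rng.normal(0, LATENT_SD["cell_radius"])),
        "cell_density": max(5.0, st.density + rng.normal(0, LATENT_SD["cell_density"])),
        "hue_shift": rng.normal(0, LATENT_SD["hue_shift"]),
    }


def make_tissue_image(class_idx: int, latents: dict[str, float], size: int = 1024,
                      seed: int | np.random.Generator = 0,
                      styles: list[ClassStyle] = DEFAULT_STYLES,
                      pixel_noise: float = 3.0) -> np.ndarray:
    """Render one slide: overlapping disk cells on a white background.

    The number of cells is ``density * size^2 / 1e4``; each cell's radius is
    the latent radius with +-20% per-cell jitter; the cell color is the class
    palette color shifted along the red-blue axis by the hue latent.
    Deterministic for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = np.full((size, size, 3), 255.0, dtype=np.float32)
    st = styles[class_idx]
    h = HUE_GAIN * latents["hue_shift"]
    base = np.array([st.color[0] + h, st.color[1], st.color[2] - h], dtype=np.float32)
    n_cells = int(round(latents["cell_density"] * size * size / 1e4))
    xs = rng.uniform(0, size, n_cells)
    ys = rng.uniform(0, size, n_cells)
    radii = latents["cell_radius"] * rng.uniform(0.8, 1.2, n_cells)
    shade = rng.uniform(0.85, 1.1, n_cells)   # per-cell staining intensity
    for cx, cy, r, s in zip(xs, ys, radii, shade):
        x0, x1 = int(max(0, cx - r)), int(min(size, cx + r + 1))
        y0, y1 = int(max(0, cy - r)), int(min(size, cy + r + 1))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.ogrid[y0:y1, x0:x1]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] = np.clip(base * s, 0, 255)
    if pixel_noise > 0:
        img += rng.normal(0, pixel_noise, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def default_gene_specs(n_direct: int = 20, n_marker: int = 20, n_null: int = 20,
                       n_classes: int = 4,
                       rng: np.random.Generator | None = None) -> list[GeneSpec]:
    """The standard 60-gene panel: direct genes cycle over the three latents;
    marker genes get a random class-mean pattern with a 3-log2 spread."""
    rng = rng or np.random.default_rng(0)
    specs = []
    for i in range(n_direct):
        specs.append(GeneSpec(f"DIR{i:03d}", "direct",
                              target=DIRECT_TARGETS[i % len(DIRECT_TARGETS)]))
    base_pattern = np.linspace(-1.5, 1.5, n_classes)
    for i in range(n_marker):
        pattern = rng.permutation(base_pattern)
        specs.append(GeneSpec(f"MRK{i:03d}", "tissue_marker",
                              class_means=tuple(8.0 + 2.0 * pattern), sigma=0.7))
    for i in range(n_null):
        specs.append(GeneSpec(f"NUL{i:03d}", "null", intercept=6.0, sigma=1.0))
    return specs


def make_expression(latent_table: pd.DataFrame, class_labels: pd.Series,
                    gene_specs: list[GeneSpec], rng: np.random.Generator,
                    duplicate_fraction: float = 0.1
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the raw genes x samples expression matrix plus sample metadata.

    ``latent_table`` is slides x latents; direct genes use the realized
    (standardized across slides) latent values, so their stated true
    correlation with the latent holds by construction up to sampling noise.
    Returns (raw expression E = 2^x - 1, metadata with sample/slide_id/tissue).
    """
    slides = list(latent_table.index)
    n = len(slides)
    z = (latent_table - latent_table.mean()) / latent_table.std(ddof=0)
    n_dup = int(round(duplicate_fraction * n))
    dup_slides = set(rng.choice(slides, size=n_dup, replace=False)) if n_dup else set()

    samples, sample_slide = [], []
    for s in slides:
        reps = 2 if s in dup_slides else 1
        for r in range(reps):
            samples.append(f"{s}_r{r + 1}")
            sample_slide.append(s)
    class_idx = class_labels.loc[sample_slide].to_numpy()

    x = np.zeros((len(gene_specs), len(samples)))
    for gi, gs in enumerate(gene_specs):
        if gs.gtype == "direct":
            mean = gs.intercept + gs.amplitude * z[gs.target].loc[sample_slide].to_numpy()
        elif gs.gtype == "tissue_marker":
            mean = np.asarray(gs.class_means)[class_idx]
        else:
            mean = np.full(len(samples), gs.intercept)
        x[gi] = mean + rng.normal(0, gs.sigma, len(samples))
    x = np.clip(x, 0.0, None)
    expr = pd.DataFrame(2.0 ** x - 1.0, index=[g.gene for g in gene_specs],
                        columns=samples)
    meta = pd.DataFrame({"sample": samples, "slide_id": sample_slide,
                         "tissue": [DEFAULT_STYLES[c].name if c < len(DEFAULT_STYLES)
                                    else f"class{c}" for c in class_idx]})
    return expr, meta


@dataclass
class SyntheticDataset:
    slides: list[SlideRecord]
    latents: pd.DataFrame            # slides x latents
    expression: pd.DataFrame         # genes x samples, raw scale
    metadata: pd.DataFrame           # sample, slide_id, tissue
    ground_truth: pd.DataFrame       # gene, gene_type, target_latent, true_corr
    gene_specs: list[GeneSpec] = field(repr=False, default_factory=list)

    def write(self, out_dir: str) -> None:
        """Export slide PNGs + the manifest/TSV formats the real-data path reads."""
        import os
        from PIL import Image
        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for s in self.slides:
            fname = f"{s.slide_id}.png"
            Image.fromarray(s.image).save(os.path.join(out_dir, fname))
            rows.append({"slide_id": s.slide_id, "path": fname,
                         "tissue": s.tissue, "split": s.split})
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "slides.tsv"),
                                  sep="\t", index=False)
        self.expression.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
        self.metadata.to_csv(os.path.join(out_dir, "metadata.tsv"),
                             sep="\t", index=False)
        self.ground_truth.to_csv(os.path.join(out_dir, "ground_truth.tsv"),
                                 sep="\t", index=False)
        self.latents.to_csv(os.path.join(out_dir, "latents.tsv"), sep="\t")


def generate_dataset(n_classes: int = 4, slides_per_class: int = 30,
                     image_size: int = 1024, gene_specs: list[GeneSpec] | None = None,
                     seed: int = 0, duplicate_fraction: float = 0.1,
                     styles: list[ClassStyle] = DEFAULT_STYLES) -> SyntheticDataset:
    """The desk-scale study recipe: by default 4 classes x 30 slides of
    1024x1024 px (4 full tiles each) and a 60-gene panel (20 direct /
    20 tissue-marker / 20 null). Fully deterministic per seed."""
    if n_classes < 2 or n_classes > len(styles):
        raise ValueError(f"n_classes must be in [2, {len(styles)}]")
    master = np.random.default_rng(seed)
    if gene_specs is None:
        gene_specs = default_gene_specs(n_classes=n_classes, rng=master)
    slides, lat_rows, labels = [], [], {}
    for c in range(n_classes):
        for i in range(slides_per_class):
            sid = f"S{c}{i:03d}"
            lat = sample_latents(c, master, styles)
            img = make_tissue_image(c, lat, image_size, master, styles)
            slides.append(SlideRecord(sid, styles[c].name, image=img))
            lat_rows.append({"slide_id": sid, **lat})
            labels[sid] = c
    latents = pd.DataFrame(lat_rows).set_index("slide_id")
    class_labels = pd.Series(labels)
    expr, meta = make_expression(latents, class_labels, gene_specs, master,
                                 duplicate_fraction)
    truth = pd.DataFrame({
        "gene": [g.gene for g in gene_specs],
        "gene_type": [g.gtype for g in gene_specs],
        "target_latent": [g.target or "" for g in gene_specs],
        "true_corr": [g.true_corr for g in gene_specs],
    })
    return SyntheticDataset(slides, latents, expr, meta, truth, gene_specs)
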