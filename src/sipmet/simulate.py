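"""Forward simulation of every input the pipeline consumes.

All generators are pure functions of (config, seed): gradient density/DNA
profiles with delta13C mixing, labeled and unlabeled community count
tables with planted active taxa, measured isotopologue clusters, and a
linked bundle in which planted (taxon, metabolite) pairs share a latent
factor. Ground truth is returned alongside so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import CountTable, TaxonomyMap
from .errors import ParameterError
from .isocorrect import (
    NATURAL_13C,
    DEFAULT_TRACER_PURITY,
    IsotopologueVector,
    build_correction_matrix,
)
from .sip import FractionRecord

# Fungal genera used for synthetic taxonomy assignments, with lineages.
GENUS_LINEAGES: dict[str, tuple[str, str, str, str, str]] = {
    # genus -> (kingdom, phylum, class, order, family)
    "Cladosporium": ("Fungi", "Ascomycota", "Dothideomycetes", "Capnodiales", "Davidiellaceae"),
    "Aureobasidium": ("Fungi", "Ascomycota", "Dothideomycetes", "Dothideales", "Dothioraceae"),
    "Cyberlindnera": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Phaffomycetaceae"),
    "Candida": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Debaryomycetaceae"),
    "Saccharomyces": ("Fungi", "Ascomycota", "Saccharomycetes", "Saccharomycetales", "Saccharomycetaceae"),
    "Aspergillus": ("Fungi", "Ascomycota", "Eurotiomycetes", "Eurotiales", "Trichocomaceae"),
    "Penicillium": ("Fungi", "Ascomycota", "Eurotiomycetes", "Eurotiales", "Trichocomaceae"),
    "Alternaria": ("Fungi", "Ascomycota", "Dothideomycetes", "Pleosporales", "Pleosporaceae"),
    "Malassezia": ("Fungi", "Basidiomycota", "Malasseziomycetes", "Malasseziales", "Malasseziaceae"),
    "Sarocladium": ("Fungi", "Ascomycota", "Sordariomycetes", "Hypocreales", "Sarocladiaceae"),
    "Pezoloma": ("Fungi", "Ascomycota", "Leotiomycetes", "Helotiales", "Helotiaceae"),
}

#: Default metabolite panel: name -> (n_carbons, baseline labeling p).
DEFAULT_METABOLITES: dict[str, tuple[int, float]] = {
    "F6P": (6, 0.55), "FBP": (6, 0.50), "G6P": (6, 0.45), "6-PG": (6, 0.40),
    "PEP": (3, 0.35), "Gly3P": (3, 0.30), "Lact": (3, 0.25), "Cit": (6, 0.20),
    "a-KG": (5, 0.15), "Succ": (4, 0.18), "Mala": (4, 0.22),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    seed: int
    active_otu_ids: tuple[str, ...]
    heavy_shift_factor: float
    contaminant_otu_ids: tuple[str, ...] = ()
    metabolite_labeling: dict = field(default_factory=dict)
    planted_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if set(self.active_otu_ids) & set(self.contaminant_otu_ids):
            raise ParameterError("active and contaminant OTU sets must be disjoint")
        if self.heavy_shift_factor < 1:
            raise ParameterError("heavy_shift_factor must be >= 1")


def gen_gradient(
    labeled_fraction: float,
    n_fractions: int = 12,
    seed: int = 0,
    density_span: tuple[float, float] = (1.66, 1.73),
    light_center: float = 1.685,
    heavy_center: float = 1.715,
    bump_sd: float = 0.008,
    delta_baseline: tuple[float, float] = (-38.5, -35.5),
    delta_labeled: float = 50.0,
    dna_scale: float = 20.0,
    noise_sd: float = 0.05,
    background: float = 0.03,
) -> list[FractionRecord]:
    """Simulate a buoyant-density gradient profile.

    DNA concentration is a two-bump mixture: a light bump (unlabeled DNA)
    and a heavy bump weighted by ``labeled_fraction``; multiplicative
    log-normal noise is applied per bump. delta13C at each fraction is the
    DNA-weighted mix of a monotonically rising unlabeled baseline and the
    strongly positive labeled value, so an unlabeled gradient has no
    interior delta13C peak while a labeled one peaks in the heavy window.
    """
    if not (0.0 <= labeled_fraction <= 1.0):
        raise ParameterError(f"labeled_fraction={labeled_fraction} outside [0, 1]")
    if n_fractions < 8:
        raise ParameterError(f"need >= 8 fractions, got {n_fractions}")
    rng = np.random.default_rng(seed)
    lo, hi = density_span
    densities = np.linspace(lo, hi, n_fractions)
    b0, b1 = delta_baseline
    baseline = b0 + (b1 - b0) * (densities - lo) / (hi - lo)

    def bump(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((densities - center) / bump_sd) ** 2)

    c_light = (1.0 - labeled_fraction) * bump(light_center)
    c_heavy = labeled_fraction * bump(heavy_center)
    c_light = c_light * np.exp(rng.normal(0.0, noise_sd, n_fractions))
    c_heavy = c_heavy * np.exp(rng.normal(0.0, noise_sd, n_fractions))
    # broad unlabeled smear spanning the whole gradient: keeps delta13C at
    # baseline far from the bumps so a labeled gradient has an interior peak
    c_back = np.full(n_fractions, background)
    total = c_light + c_heavy + c_back
    delta = ((c_light + c_back) * baseline + c_heavy * delta_labeled) / total
    dna = dna_scale * total + 0.05
    return [
        FractionRecord(i, float(round(d, 4)), float(dna[i]), float(delta[i]))
        for i, d in enumerate(densities)
    ]


def binomial_labeling(n_carbons: int, p: float, purity: float = 1.0) -> np.ndarray:
    """Binom(n, p * purity) labeling distribution (impurity thins the labeling)."""
    from scipy.stats import binom

    q = p * purity
    if not (0.0 <= q <= 1.0):
        raise ParameterError(f"labeling probability {q} outside [0, 1]")
    return binom.pmf(np.arange(n_carbons + 1), n_carbons, q)


def gen_cid(
    n_carbons: int,
    true_labeling,
    purity: float = DEFAULT_TRACER_PURITY,
    natural_13C: float = NATURAL_13C,
    noise_sd: float = 0.0,
    seed: int = 0,
    metabolite_id: str = "met",
) -> tuple[IsotopologueVector, np.ndarray]:
    """Forward-convolve a true labeling distribution into a measured cluster.

    ``true_labeling`` is either a simplex vector x (used as-is) or a scalar
    binomial probability p, in which case x = Binom(n, p * purity): the
    tracer impurity thins the intended labeling, so the recoverable mean
    enrichment is p * purity. The measured vector is m = A x plus
    truncated Gaussian noise, renormalized. Returns (measured, x_true).
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if np.isscalar(true_labeling):
        x = binomial_labeling(n_carbons, float(true_labeling), purity)
    else:
        x = np.asarray(true_labeling, dtype=float)
        if x.size != n_carbons + 1 or np.any(x < 0) or not np.isclose(x.sum(), 1.0):
            raise ParameterError("true_labeling must be a simplex vector of length n+1")
    model = build_correction_matrix(n_carbons, natural_13C, purity)
    m = model.matrix @ x
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = np.clip(m + rng.normal(0.0, noise_sd, m.size), 0.0, None)
        if m.sum() <= 0:  # pragma: no cover - astronomically unlikely
            m = model.matrix @ x
    m = m / m.sum()
    return IsotopologueVector(metabolite_id, n_carbons, m), x


def _composition(rng: np.random.Generator, n_otus: int, concentration: float) -> np.ndarray:
    return rng.dirichlet(np.full(n_otus, concentration))


def gen_community(
    n_otus: int = 200,
    n_active: int = 5,
    heavy_shift_factor: float = 5.0,
    depth: int = 3248,
    n_replicates: int = 3,
    seed: int = 0,
    sexes: tuple[str, ...] = ("F",),
    times: tuple[int, ...] = (4,),
    concentration: float = 0.3,
    n_contaminants: int = 0,
    active_min_weight: float = 0.01,
    include_male_30h: bool = True,
    active_weight_gain: np.ndarray | None = None,
) -> tuple[CountTable, TaxonomyMap, SimulationTruth]:
    """Simulate composite heavy/light count tables with planted active taxa.

    A long-tailed Dirichlet base composition is shared by all samples.
    Under the 13C treatment the planted active OTUs' weights are multiplied
    by ``heavy_shift_factor`` in heavy composites (then renormalized);
    the 12C treatment and all light composites keep the base composition.
    Counts are multinomial at exactly ``depth`` per sample. When
    ``n_contaminants`` > 0, dedicated low-abundance OTUs dominate a
    negative-control sample. Active OTUs are planted among OTUs whose base
    weight exceeds ``active_min_weight`` so they are detectable at the
    given depth. ``active_weight_gain``, if given, is a per-(sex, time,
    replicate)-unit multiplier array modulating the shift (used to plant
    taxa-metabolite links).

    Returns (CountTable, TaxonomyMap, SimulationTruth).
    """
    if n_active >= n_otus:
        raise ParameterError("n_active must be < n_otus")
    if depth < 500:
        raise ParameterError("depth must be >= 500")
    if heavy_shift_factor < 1:
        raise ParameterError("heavy_shift_factor must be >= 1")
    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    base = _composition(rng, n_otus, concentration)

    contaminant_idx = np.array([], dtype=int)
    if n_contaminants > 0:
        # contaminants: dedicated OTUs made vanishingly rare in biology
        order = np.argsort(base)
        contaminant_idx = order[:n_contaminants]
        base[contaminant_idx] = 1e-7
        base = base / base.sum()

    eligible = np.setdiff1d(np.where(base > active_min_weight)[0], contaminant_idx)
    if eligible.size < n_active:
        eligible = np.setdiff1d(np.argsort(base)[::-1][: n_active + n_contaminants],
                                contaminant_idx)[:n_active]
    active_idx = (rng.choice(eligible, size=n_active, replace=False)
                  if n_active > 0 else np.array([], dtype=int))

    units = [
        (sex, t)
        for sex in sexes
        for t in times
        if include_male_30h or not (sex == "M" and t == 30)
    ]
    cols: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    unit_index = 0
    for sex, t in units:
        for rep in range(1, n_replicates + 1):
            gain = 1.0
            if active_weight_gain is not None:
                gain = float(np.asarray(active_weight_gain).ravel()[unit_index])
            unit_index += 1
            shifted = base.copy()
            if n_active > 0:
                shifted[active_idx] *= 1.0 + (heavy_shift_factor - 1.0) * gain
                shifted = shifted / shifted.sum()
            for treatment in ("12C", "13C"):
                for fc in ("heavy", "light"):
                    name = f"{sex}_t{t}_r{rep}_{treatment}_{fc}"
                    comp = shifted if (treatment == "13C" and fc == "heavy") else base
                    cols[name] = rng.multinomial(depth, comp)
                    meta_rows[name] = {
                        "sex": sex, "time_h": t, "treatment": treatment,
                        "fraction_class": fc, "replicate": rep,
                        "is_control": False,
                    }
    if n_contaminants > 0:
        ctrl = np.zeros(n_otus)
        ctrl[contaminant_idx] = 0.997 / n_contaminants
        others = np.setdiff1d(np.arange(n_otus), contaminant_idx)
        ctrl[others] = 0.003 * base[others] / base[others].sum()
        cols["NEG_CTRL"] = rng.multinomial(depth, ctrl)
        meta_rows["NEG_CTRL"] = {
            "sex": "none", "time_h": -1, "treatment": "none",
            "fraction_class": "none", "replicate": 0, "is_control": True,
        }

    counts = pd.DataFrame(cols, index=otu_ids)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    table = CountTable(counts, meta)

    genera = list(GENUS_LINEAGES)
    lineages = {}
    for i, otu in enumerate(otu_ids):
        genus = genera[i % len(genera)]
        kingdom, phylum, klass, order_, family = GENUS_LINEAGES[genus]
        boot = float(rng.integers(80, 101))
        lineages[otu] = {
            "kingdom": (kingdom, 100.0), "phylum": (phylum, 100.0),
            "class": (klass, 95.0), "order": (order_, 90.0),
            "family": (family, boot), "genus": (genus, boot),
        }
    taxonomy = TaxonomyMap(lineages)

    truth = SimulationTruth(
        seed=seed,
        active_otu_ids=tuple(otu_ids[i] for i in sorted(active_idx)),
        heavy_shift_factor=heavy_shift_factor,
        contaminant_otu_ids=tuple(otu_ids[i] for i in sorted(contaminant_idx)),
    )
    return table, taxonomy, truth


@dataclass(frozen=True)
class Scenario:
    """Configuration of one simulated study."""

    n_otus: int = 200
    n_active: int = 5
    heavy_shift_factor: float = 5.0
    depth: int = 4000
    n_replicates: int = 3
    sexes: tuple[str, ...] = ("F", "M")
    times: tuple[int, ...] = (4, 10, 30)
    concentration: float = 0.3
    n_contaminants: int = 3
    include_male_30h: bool = False
    labeled_fraction: float = 0.3
    metabolites: dict = field(default_factory=lambda: dict(DEFAULT_METABOLITES))
    planted_pairs: tuple[tuple[str, str], ...] = ()
    link_strength: float = 0.9
    cid_noise_sd: float = 0.002
    tracer_purity: float = DEFAULT_TRACER_PURITY
    natural_13C: float = NATURAL_13C


def gen_linked_dataset(scenario: Scenario, seed: int = 0) -> dict:
    """Simulate the full input bundle with linked taxa-metabolite structure.

    Planted (genus, metabolite) pairs share one latent factor per
    observation unit (sex, time, replicate): the factor modulates both the
    active genus' heavy-shift and the metabolite's labeling probability,
    so the pair correlates across units. Returns a dict with keys
    ``community``, ``taxonomy``, ``gradients``, ``isotopologues`` and
    ``truth``.
    """
    root = np.random.SeedSequence(seed)
    ss_comm, ss_grad, ss_cid, ss_latent = root.spawn(4)
    rng_latent = np.random.default_rng(ss_latent)

    units = [
        (sex, t)
        for sex in scenario.sexes
        for t in scenario.times
        if scenario.include_male_30h or not (sex == "M" and t == 30)
    ]
    n_units = len(units) * scenario.n_replicates
    latent = rng_latent.uniform(0.2, 1.0, size=n_units)
    gain = latent if scenario.planted_pairs else np.ones(n_units)

    table, taxonomy, truth = gen_community(
        n_otus=scenario.n_otus,
        n_active=scenario.n_active,
        heavy_shift_factor=scenario.heavy_shift_factor,
        depth=scenario.depth,
        n_replicates=scenario.n_replicates,
        seed=int(np.random.default_rng(ss_comm).integers(2**31)),
        sexes=scenario.sexes,
        times=scenario.times,
        concentration=scenario.concentration,
        n_contaminants=scenario.n_contaminants,
        include_male_30h=scenario.include_male_30h,
        active_weight_gain=gain,
    )

    # resolve planted pairs onto actually-active genera
    active_genera = sorted({taxonomy.label(o, "genus") for o in truth.active_otu_ids})
    planted = []
    for genus, met in scenario.planted_pairs:
        if genus not in active_genera or met not in scenario.metabolites:
            raise ParameterError(
                f"planted pair ({genus}, {met}) does not match an active genus "
                f"({active_genera}) and a panel metabolite")
        planted.append((genus, met))

    gradients = {}
    rng_grad = np.random.default_rng(ss_grad)
    for sex, t in units:
        for treatment, lf in (("12C", 0.0), ("13C", scenario.labeled_fraction)):
            gradients[(sex, t, treatment)] = gen_gradient(
                lf, seed=int(rng_grad.integers(2**31)))

    linked_mets = {met for _, met in planted}
    rng_cid = np.random.default_rng(ss_cid)
    rows = []
    met_truth = {}
    u = 0
    for sex, t in units:
        for rep in range(1, scenario.n_replicates + 1):
            z = latent[u]
            u += 1
            for met, (n_c, base_p) in scenario.metabolites.items():
                if met in linked_mets:
                    p = float(np.clip(scenario.link_strength * z, 0.0, 1.0))
                else:
                    p = float(np.clip(
                        base_p + rng_cid.normal(0.0, 0.02), 0.0, 1.0))
                vec, x_true = gen_cid(
                    n_c, p,
                    purity=scenario.tracer_purity,
                    natural_13C=scenario.natural_13C,
                    noise_sd=scenario.cid_noise_sd,
                    seed=int(rng_cid.integers(2**31)),
                    metabolite_id=met,
                )
                met_truth[(sex, t, rep, met)] = p * scenario.tracer_purity
                row = {
                    "metabolite_id": met, "n_carbons": n_c, "sex": sex,
                    "time_h": t, "compartment": "gut", "replicate": rep,
                }
                for k, v in enumerate(vec.intensities):
                    row[f"M{k}"] = v
                rows.append(row)
    max_n = max(n for n, _ in scenario.metabolites.values())
    columns = (["metabolite_id", "n_carbons", "sex", "time_h", "compartment",
                "replicate"] + [f"M{k}" for k in range(max_n + 1)])
    isotopologues = pd.DataFrame(rows, columns=columns)

    truth = replace(
        truth,
        seed=seed,
        metabolite_labeling=met_truth,
        planted_pairs=tuple(planted),
    )
    return {
        "community": table,
        "taxonomy": taxonomy,
        "gradients": gradients,
        "isotopologues": isotopologues,
        "truth": truth,
    }
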