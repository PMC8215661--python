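"""Synthetic soil-eDNA metabarcoding study generator.

Emulates the design of an Alpine elevational-gradient survey: several sites
whose elevation sub-ranges tile 1,250-2,940 m in ~200 m steps, two soil
horizons (litter, deep), PCR triplicates per sample, extraction and PCR
blanks, positive controls carrying a halving-dilution mock community, spiked
reagent contaminants, and a configurable fraction of failed (low-depth) PCRs.

Taxon abundances follow Gaussian niche response curves over the environmental
space (specialists) or flat responses (generalists); read counts per PCR are
Dirichlet-multinomial around the niche-model expectations so that
overdispersion relative to a plain multinomial is tunable.  Every generated
object is a deterministic function of the configuration, including its seed,
and the true niches are returned as ground truth for parameter-recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import MOTUTable, validate_pcrs

#: Continuous environmental variables, Elevation first (it anchors the copula).
CONTINUOUS_VARS = (
    "Elevation",
    "pH",
    "Nitrogen",
    "Carbon",
    "C_N_ratio",
    "OrganicMatter",
    "FDD",
    "CWD",
    "DTR",
)

#: Marginal (mean, sd, lower clip, upper clip) for each continuous variable.
#: Units: Elevation m a.s.l.; pH unitless; Nitrogen/Carbon/OrganicMatter
#: content (%); C/N ratio unitless; FDD degree-days; CWD water-stress index;
#: DTR deg C.
_MARGINALS = {
    "pH": (5.6, 0.7, 3.5, 8.8),
    "Nitrogen": (0.45, 0.18, 0.02, None),
    "Carbon": (8.0, 3.0, 0.3, None),
    "C_N_ratio": (14.0, 3.5, 4.0, None),
    "OrganicMatter": (16.0, 6.0, 0.5, None),
    "FDD": (250.0, 120.0, 0.0, None),
    "CWD": (55.0, 20.0, 0.0, None),
    "DTR": (10.5, 2.0, 2.0, None),
}

_SITE_NAMES = ("CHA", "LOR", "ANT", "RIS", "VCH")

#: Default class mix; proportions follow the read shares of the four
#: Chlorophyta classes reported for this kind of alpine soil survey
#: (82.3 / 11.1 / 1.6 / 0.02 %), renormalised to sum to one.
DEFAULT_CLASS_MIX = {
    "Trebouxiophyceae": 0.8661,
    "Chlorophyceae": 0.1168,
    "Ulvophyceae": 0.0169,
    "Pedinophyceae": 0.0002,
}


def default_env_correlation() -> pd.DataFrame:
    """Default correlation matrix over the continuous variables.

    Built from a two-factor loading structure (an elevation/climate factor and
    a soil-fertility factor), which guarantees positive semi-definiteness and
    yields the moderate multicollinearity (fertility block r ~ 0.8) needed to
    exercise iterative VIF selection.
    """
    loadings = {
        "Elevation": (0.90, -0.30),
        "pH": (-0.40, 0.30),
        "Nitrogen": (-0.15, 0.80),
        "Carbon": (-0.12, 0.96),
        "C_N_ratio": (0.20, 0.40),
        "OrganicMatter": (-0.08, 0.96),
        "FDD": (0.80, 0.00),
        "CWD": (-0.55, 0.10),
        "DTR": (0.50, 0.00),
    }
    L = np.array([loadings[v] for v in CONTINUOUS_VARS])
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=CONTINUOUS_VARS, columns=CONTINUOUS_VARS)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study design.

    Defaults reproduce the field design: 5 sites tiling 1,250-2,940 m in
    200 m steps (each site spanning ~1,000 m), litter + deep horizons,
    triplicate PCRs, blanks and positive controls, a 13-species halving mock
    community.
    """

    n_sites: int = 5
    elevation_range: tuple[float, float] = (1250.0, 2940.0)
    elevation_step: float = 200.0
    site_span: float = 1000.0
    horizons: tuple[str, ...] = ("litter", "deep")
    n_replicates: int = 3
    n_taxa: int = 60
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    specialist_fraction: float = 0.7
    offtarget_fraction: float = 0.15
    specialist_budget: float = 0.5
    optima_extension: float = 300.0
    depth_mean: float = 20000.0
    depth_sigma: float = 0.3
    depth_dispersion: float = 0.005
    fail_rate: float = 0.05
    fail_depth_max: int = 100
    n_contaminants: int = 3
    contaminant_intensity: float = 2000.0
    contaminant_spill: float = 0.001
    blank_leak_mean: float = 0.0
    n_extraction_blanks: int = 2
    n_pcr_blanks: int = 2
    n_positives: int = 2
    mock_size: int = 13
    mock_dilution: float = 0.5
    marker: str = "Chlo01"
    env_correlation: pd.DataFrame | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range
        if not lo < hi:
            raise ValueError("elevation_range must satisfy min < max")
        if self.elevation_step <= 0:
            raise ValueError("elevation_step must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if not self.class_mix:
            raise ValueError("class_mix must name at least one class")
        total = float(sum(self.class_mix.values()))
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mix proportions must sum to 1 (got {total})")
        if not 0.0 <= self.fail_rate <= 1.0:
            raise ValueError("fail_rate must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible random stream for one generator stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth niche of one simulated taxon.

    ``optimum`` and ``breadth`` map environmental variables to the centre and
    Gaussian standard deviation of the response curve; generalists respond
    flat across the whole sampled range.  ``min_elevation`` imposes a hard
    floor (e.g. a snow-alga-like taxon absent below ~2,000 m).
    """

    taxon_id: str
    class_label: str
    genus: str
    species: str
    clade_path: str
    optimum: Mapping[str, float]
    breadth: Mapping[str, float]
    peak_abundance: float
    generalist_flag: bool
    min_elevation: float | None = None

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.breadth.values()):
            raise ValueError("niche breadth must be positive for every variable")

    def expected_abundance(self, env_row: Mapping[str, float]) -> float:
        """Expected (unnormalised) abundance at one sample's environment."""
        if (
            self.min_elevation is not None
            and float(env_row["Elevation"]) < self.min_elevation
        ):
            return 0.0
        a = self.peak_abundance
        if self.generalist_flag:
            return a
        for var, opt in self.optimum.items():
            x = float(env_row[var])
            b = self.breadth[var]
            a *= math.exp(-0.5 * ((x - opt) / b) ** 2)
        return a


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------

def _site_layout(config: GeneratorConfig) -> list[tuple[str, np.ndarray]]:
    lo, hi = config.elevation_range
    span = min(config.site_span, hi - lo)
    n_levels = int(math.floor(span / config.elevation_step + 1e-9)) + 1
    if config.n_sites == 1:
        mins = np.array([lo])
    else:
        mins = np.linspace(lo, hi - span, config.n_sites)
    names = [
        _SITE_NAMES[i] if i < len(_SITE_NAMES) else f"S{i + 1:02d}"
        for i in range(config.n_sites)
    ]
    out = []
    for name, m in zip(names, mins):
        elevs = np.round(m + config.elevation_step * np.arange(n_levels))
        out.append((name, elevs))
    return out


def generate_env(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the per-sample environmental table.

    One row per site x elevation level x horizon.  Elevation is fixed by the
    sampling design; the remaining continuous variables are drawn from a
    Gaussian copula conditioned on the standardised elevation so that an
    arbitrary (positive semi-definite) correlation matrix can be imposed.
    Litter rows receive a fertility shift (higher Nitrogen, Carbon, organic
    matter), and Environment is forest below 1,800 m, open-area above.
    """
    rng = config.rng(0)
    R = (
        default_env_correlation()
        if config.env_correlation is None
        else config.env_correlation.loc[list(CONTINUOUS_VARS), list(CONTINUOUS_VARS)]
    )
    Rm = np.asarray(R, dtype=float)
    eigvals = np.linalg.eigvalsh((Rm + Rm.T) / 2)
    if eigvals.min() < -1e-8:
        raise ValueError(
            "environmental correlation matrix is not positive semi-definite"
        )

    rows = []
    for site, elevs in _site_layout(config):
        for e in elevs:
            for hor in config.horizons:
                rows.append((f"{site}_{int(e)}_{hor}", site, float(e), hor))
    index = [r[0] for r in rows]
    site_col = [r[1] for r in rows]
    elev = np.array([r[2] for r in rows])
    horizon = [r[3] for r in rows]
    n = len(rows)

    # conditional Gaussian given the (standardised) design elevation
    z_elev = (elev - elev.mean()) / max(elev.std(), 1e-12)
    r1 = Rm[0, 1:]
    S = Rm[1:, 1:] - np.outer(r1, r1)
    w, V = np.linalg.eigh((S + S.T) / 2)
    w = np.clip(w, 0.0, None)
    A = V @ np.diag(np.sqrt(w))
    z_rest = z_elev[:, None] * r1[None, :] + rng.standard_normal((n, len(r1))) @ A.T

    env = pd.DataFrame(index=pd.Index(index, name="sample_id"))
    env["Site"] = site_col
    env["Elevation"] = elev
    env["Horizon"] = horizon
    env["Environment"] = np.where(elev < 1800.0, "forest", "open-area")
    litter = np.array([h == "litter" for h in horizon])
    for j, var in enumerate(CONTINUOUS_VARS[1:]):
        mean, sd, lo_c, hi_c = _MARGINALS[var]
        x = mean + sd * z_rest[:, j]
        if var in ("Nitrogen", "Carbon", "OrganicMatter"):
            x = x + litter * 0.7 * sd  # litter horizon is richer
        if lo_c is not None:
            x = np.maximum(x, lo_c)
        if hi_c is not None:
            x = np.minimum(x, hi_c)
        env[var] = np.round(x, 4)
    return env


# ---------------------------------------------------------------------------
# taxa
# ---------------------------------------------------------------------------

#: Class-specific shifts of specialist optima (m elevation, pH units): the
#: Chlorophyceae niche centre sits higher on both gradients than the
#: Trebouxiophyceae one, giving the two dominant classes distinct niches.
#: Shifts are close to mean-zero under the default class mix so the pooled
#: specialist share stays flat along the gradients.
_CLASS_NICHE_SHIFT = {
    "Chlorophyceae": (300.0, 0.6),
    "Trebouxiophyceae": (-40.0, -0.08),
}


def generate_taxa(config: GeneratorConfig) -> list[TrueNiche]:
    """Draw ground-truth niches: target-clade specialists/generalists plus a
    fraction of off-target (non-Chlorophyta) taxa that exercise the clade
    filter downstream."""
    if config.n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    rng = config.rng(1)
    lo, hi = config.elevation_range
    width = hi - lo
    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)

    taxa: list[TrueNiche] = []
    n_off = int(round(config.offtarget_fraction * config.n_taxa))
    for i in range(config.n_taxa):
        taxon_id = f"T{i + 1:03d}"
        off_target = i < n_off
        if off_target:
            cls = "Fungi" if rng.random() < 0.6 else "Streptophyta"
            clade = f"Eukaryota;{cls}"
        else:
            cls = classes[rng.choice(len(classes), p=probs)]
            clade = f"Eukaryota;Chlorophyta;{cls}"
        genus = f"Genus{i + 1:03d}"
        species = f"{genus.lower()}_sp"
        peak = float(rng.lognormal(0.0, 1.0))
        specialist = (not off_target) and rng.random() < config.specialist_fraction
        if specialist:
            # optima drawn from a gradient extended past the sampled range so
            # that the pooled specialist share stays flat across samples
            # (avoids boundary depletion coupling every taxon to elevation);
            # the two dominant classes differ in their preferences
            # (Chlorophyceae toward higher elevation and pH)
            ext = config.optima_extension
            d_elev, d_ph = _CLASS_NICHE_SHIFT.get(cls, (0.0, 0.0))
            optimum = {
                "Elevation": float(
                    np.clip(rng.uniform(lo - ext, hi + ext) + d_elev, lo - ext, hi + ext)
                ),
                "pH": float(rng.uniform(4.2, 7.2) + d_ph),
            }
            breadth = {
                "Elevation": float(rng.uniform(130.0, 320.0)),
                "pH": float(rng.uniform(0.5, 1.5)),
            }
            generalist = False
        else:
            optimum = {"Elevation": (lo + hi) / 2, "pH": 5.6}
            breadth = {"Elevation": 10.0 * width, "pH": 50.0}
            generalist = True
        taxa.append(
            TrueNiche(
                taxon_id=taxon_id,
                class_label=cls,
                genus=genus,
                species=species,
                clade_path=f"{clade};{genus};{species}",
                optimum=optimum,
                breadth=breadth,
                peak_abundance=peak,
                generalist_flag=generalist,
            )
        )
    return taxa


def niches_to_frame(taxa: Sequence[TrueNiche]) -> pd.DataFrame:
    """Flatten ground-truth niches to a table (for the simulate CLI output)."""
    rows = []
    for t in taxa:
        rows.append(
            {
                "taxon_id": t.taxon_id,
                "class": t.class_label,
                "genus": t.genus,
                "species": t.species,
                "generalist": t.generalist_flag,
                "peak_abundance": t.peak_abundance,
                "opt_Elevation": t.optimum.get("Elevation", np.nan),
                "breadth_Elevation": t.breadth.get("Elevation", np.nan),
                "opt_pH": t.optimum.get("pH", np.nan),
                "breadth_pH": t.breadth.get("pH", np.nan),
                "min_elevation": t.min_elevation,
            }
        )
    return pd.DataFrame(rows).set_index("taxon_id")


# ---------------------------------------------------------------------------
# mock community
# ---------------------------------------------------------------------------

def mock_community(n_species: int, dilution: float) -> np.ndarray:
    """Positive-control concentration vector: each species at `dilution` times
    the previous one, normalised to sum to 1."""
    if n_species < 1:
        raise ValueError("n_species must be at least 1")
    if not 0.0 < dilution <= 1.0:
        raise ValueError("dilution must lie in (0, 1]")
    conc = dilution ** np.arange(n_species, dtype=float)
    return conc / conc.sum()


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_MARKER_LENGTHS = {"Chlo01": (80, 180), "Chlo02": (91, 94), "Euka03": (80, 180)}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def expected_proportions(
    env_row, taxa: Sequence[TrueNiche], config: GeneratorConfig, det: np.ndarray
) -> np.ndarray:
    """Expected relative abundances of the real taxa in one sample.

    The community splits into two fixed read budgets: generalists share
    ``1 - specialist_budget`` in constant proportions (their relative
    frequencies do not depend on the environment), while specialists share
    ``specialist_budget`` proportionally to their Gaussian responses at the
    sample's environment.  This keeps generalists exchangeable across samples
    (an honest null for niche tests) while specialists track their optima in
    relative-frequency space.
    """
    gen_mask = np.array([t.generalist_flag for t in taxa])
    w = np.array([t.expected_abundance(env_row) for t in taxa]) * det
    gen_w = np.where(gen_mask, np.array([t.peak_abundance for t in taxa]) * det, 0.0)
    spec_w = np.where(~gen_mask, w, 0.0)
    b_spec = config.specialist_budget if spec_w.sum() > 0 else 0.0
    b_gen = (1.0 - config.specialist_budget) if gen_w.sum() > 0 else 0.0
    total_b = b_spec + b_gen
    if total_b == 0:
        return np.zeros(len(taxa))
    p = np.zeros(len(taxa))
    if b_gen > 0:
        p += gen_w / gen_w.sum() * (b_gen / total_b)
    if b_spec > 0:
        p += spec_w / spec_w.sum() * (b_spec / total_b)
    return p


def _draw_counts(
    rng: np.random.Generator, p: np.ndarray, depth: int, dispersion: float
) -> np.ndarray:
    """Dirichlet-multinomial draw with mean proportions ``p``; ``dispersion``
    -> 0 collapses to a plain multinomial."""
    counts = np.zeros(len(p), dtype=np.int64)
    if depth <= 0 or p.sum() <= 0:
        return counts
    pos = p > 0
    q = p[pos] / p[pos].sum()
    if dispersion > 0:
        q = rng.dirichlet(q / dispersion)
    counts[pos] = rng.multinomial(depth, q)
    return counts


def simulate_reads(
    env: pd.DataFrame,
    taxa: Sequence[TrueNiche],
    config: GeneratorConfig,
    detection: Mapping[str, float] | None = None,
    clade_factor: Mapping[str, float] | None = None,
    clade: str = "Chlorophyta",
) -> tuple[MOTUTable, pd.DataFrame]:
    """Simulate the MOTU x PCR count table and PCR metadata.

    ``detection`` optionally maps taxon ids to marker-specific detection
    efficiency multipliers (used to emulate a second marker observing the same
    underlying communities through different amplification biases).
    ``clade_factor`` optionally maps sample ids to a multiplier on the target
    clade's total abundance — a sample-level latent shared between markers so
    that cross-marker clade frequencies co-vary, as they do when the clade's
    biomass itself varies between soils.

    Ground truth is carried in the outputs: MOTU annotations gain boolean
    ``is_contaminant`` / ``is_mock`` columns and the PCR table a
    ``true_failed`` column.
    """
    if len(taxa) == 0:
        raise ValueError("at least one taxon is required")
    rng = config.rng(2)
    lmin, lmax = _MARKER_LENGTHS.get(config.marker, (80, 180))

    # --- MOTU ids and annotations -----------------------------------------
    motu_ids = [t.taxon_id for t in taxa]
    cont_ids = [f"C{i + 1:02d}" for i in range(config.n_contaminants)]
    mock_ids = [f"MOCK{i + 1:02d}" for i in range(config.mock_size)]
    ann_rows = []
    for t in taxa:
        seq = _random_sequence(rng, int(rng.integers(lmin, lmax + 1)))
        ann_rows.append(
            {
                "motu_id": t.taxon_id,
                "sequence": seq,
                "length": len(seq),
                "class": t.class_label,
                "genus": t.genus,
                "species": t.species,
                "clade_path": t.clade_path,
                "is_contaminant": False,
                "is_mock": False,
            }
        )
    for cid in cont_ids:
        seq = _random_sequence(rng, int(rng.integers(lmin, lmax + 1)))
        ann_rows.append(
            {
                "motu_id": cid,
                "sequence": seq,
                "length": len(seq),
                "class": "Chlorophyceae",
                "genus": "ReagentAlga",
                "species": f"reagentalga_{cid.lower()}",
                "clade_path": f"Eukaryota;Chlorophyta;Chlorophyceae;ReagentAlga;reagentalga_{cid.lower()}",
                "is_contaminant": True,
                "is_mock": False,
            }
        )
    for mid in mock_ids:
        seq = _random_sequence(rng, int(rng.integers(lmin, lmax + 1)))
        ann_rows.append(
            {
                "motu_id": mid,
                "sequence": seq,
                "length": len(seq),
                "class": "Chlorophyceae",
                "genus": "MockAlga",
                "species": f"mockalga_{mid.lower()}",
                "clade_path": f"Eukaryota;Chlorophyta;Chlorophyceae;MockAlga;mockalga_{mid.lower()}",
                "is_contaminant": False,
                "is_mock": True,
            }
        )
    annotations = pd.DataFrame(ann_rows).set_index("motu_id")
    all_ids = motu_ids + cont_ids + mock_ids
    id_pos = {m: i for i, m in enumerate(all_ids)}

    # --- PCR metadata ------------------------------------------------------
    pcr_rows = []
    for sample_id in env.index:
        for r in range(1, config.n_replicates + 1):
            pcr_rows.append((f"{sample_id}_r{r}", sample_id, r, "sample"))
    for i in range(config.n_extraction_blanks):
        for r in range(1, config.n_replicates + 1):
            pcr_rows.append((f"EXTB{i + 1}_r{r}", f"EXTB{i + 1}", r, "extraction_blank"))
    for i in range(config.n_pcr_blanks):
        for r in range(1, config.n_replicates + 1):
            pcr_rows.append((f"PCRB{i + 1}_r{r}", f"PCRB{i + 1}", r, "pcr_blank"))
    for i in range(config.n_positives):
        for r in range(1, config.n_replicates + 1):
            pcr_rows.append((f"POS{i + 1}_r{r}", f"POS{i + 1}", r, "positive"))
    pcrs = pd.DataFrame(pcr_rows, columns=["pcr_id", "sample_id", "replicate", "control_type"])
    pcrs["marker"] = config.marker
    pcrs["true_failed"] = False
    pcrs = pcrs[["pcr_id", "sample_id", "marker", "replicate", "control_type", "true_failed"]]

    det = np.ones(len(taxa))
    if detection is not None:
        det = np.array([detection.get(t.taxon_id, 1.0) for t in taxa])

    mock_p = mock_community(config.mock_size, config.mock_dilution)
    spill_total = config.n_contaminants * config.contaminant_spill

    counts = np.zeros((len(all_ids), len(pcrs)), dtype=np.int64)
    for j, rec in enumerate(pcrs.itertuples(index=False)):
        p = np.zeros(len(all_ids))
        if rec.control_type == "sample":
            row = env.loc[rec.sample_id]
            expect = expected_proportions(row, taxa, config, det)
            if clade_factor is not None:
                f = float(clade_factor.get(rec.sample_id, 1.0))
                in_clade = np.array([clade in t.clade_path for t in taxa])
                expect = np.where(in_clade, expect * f, expect)
                if expect.sum() > 0:
                    expect = expect / expect.sum()
            expect = expect * (1.0 - spill_total)
            for i, t in enumerate(taxa):
                p[id_pos[t.taxon_id]] = expect[i]
            for cid in cont_ids:
                p[id_pos[cid]] = config.contaminant_spill
            failed = rng.random() < config.fail_rate
            if failed:
                depth = int(rng.integers(0, config.fail_depth_max + 1))
                pcrs.iloc[j, pcrs.columns.get_loc("true_failed")] = True
            else:
                depth = int(
                    round(
                        rng.lognormal(
                            math.log(config.depth_mean) - config.depth_sigma**2 / 2,
                            config.depth_sigma,
                        )
                    )
                )
            counts[:, j] = _draw_counts(rng, p, depth, config.depth_dispersion)
        elif rec.control_type in ("extraction_blank", "pcr_blank"):
            for cid in cont_ids:
                counts[id_pos[cid], j] = rng.poisson(config.contaminant_intensity)
            if config.blank_leak_mean > 0:
                leak = int(rng.poisson(config.blank_leak_mean))
                if leak > 0 and len(taxa) > 0:
                    peaks = np.array([t.peak_abundance for t in taxa])
                    lp = peaks / peaks.sum()
                    leak_counts = rng.multinomial(leak, lp)
                    for i, t in enumerate(taxa):
                        counts[id_pos[t.taxon_id], j] += leak_counts[i]
        else:  # positive control: mock community only
            for i, mid in enumerate(mock_ids):
                p[id_pos[mid]] = mock_p[i]
            depth = int(
                round(
                    rng.lognormal(
                        math.log(config.depth_mean) - config.depth_sigma**2 / 2,
                        config.depth_sigma,
                    )
                )
            )
            counts[:, j] = _draw_counts(rng, p, depth, config.depth_dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(all_ids, name="motu_id"), columns=pcrs["pcr_id"].to_list())
    table = MOTUTable(annotations, counts_df)
    validate_pcrs(pcrs)
    return table, pcrs


def simulate_marker_pair(
    config: GeneratorConfig,
    detection_sigma: float = 0.8,
    clade_log_sd: float = 1.0,
) -> tuple[MOTUTable, MOTUTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Two marker tables over the same underlying communities.

    Both tables share the environment, the true niches, and a per-sample
    lognormal factor (sd ``clade_log_sd`` on the log scale) on the target
    clade's total abundance; each marker additionally observes the taxa
    through its own lognormal detection efficiency (sd ``detection_sigma``),
    emulating marker-to-marker amplification bias.  Returns
    (table_a, table_b, pcrs_a, pcrs_b, env).
    """
    env = generate_env(config)
    taxa = generate_taxa(config)
    rng = config.rng(3)
    det_a = {t.taxon_id: float(rng.lognormal(0.0, detection_sigma)) for t in taxa}
    det_b = {t.taxon_id: float(rng.lognormal(0.0, detection_sigma)) for t in taxa}
    factor = {s: float(rng.lognormal(0.0, clade_log_sd)) for s in env.index}
    table_a, pcrs_a = simulate_reads(
        env, taxa, config, detection=det_a, clade_factor=factor
    )
    config_b = replace(config, marker="Chlo02", seed=config.seed + 1)
    table_b, pcrs_b = simulate_reads(
        env, taxa, config_b, detection=det_b, clade_factor=factor
    )
    return table_a, table_b, pcrs_a, pcrs_b, env
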