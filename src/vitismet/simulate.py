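"""Synthetic direct-infusion MS experiments and qPCR Cq tables with known ground truth.

The generators reproduce the statistical structure the downstream analysis
assumes: two resistance groups of field-grown genotypes with a fixed number
of biological replicates each, log-normal multiplicative intensity noise,
ppm-scale m/z jitter, randomly missing peaks, an always-present internal
standard, and a planted set of discriminatory features with |log2 fold
change| >= 1 between groups.  The qPCR generator plants reference genes of
graded stability plus genes of interest with group-specific Cq shifts.

Every generator takes a single seed and draws from one RNG stream, so
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import MODES, RESISTANT, SUSCEPTIBLE, PeakList

#: [M+H]+ of the leucine enkephalin internal calibrant.
DEFAULT_STANDARD_MZ = 556.276575

#: Resistance classes of the eleven field-grown Vitis genotypes: the five
#: wild species, V. vinifera subsp. sylvestris and the hybrid 'Regent'
#: are resistant/partial-resistant; the remaining V. vinifera cultivars
#: (Riesling, Pinot noir, Cabernet Sauvignon, Trincadeira) susceptible.
STUDY_GENOTYPES = {
    "LAB": RESISTANT, "ROT": RESISTANT, "RIP": RESISTANT, "CAN": RESISTANT,
    "RU": RESISTANT, "SYL": RESISTANT, "REG": RESISTANT,
    "RL": SUSCEPTIBLE, "PN": SUSCEPTIBLE, "CS": SUSCEPTIBLE, "TRI": SUSCEPTIBLE,
}


def make_study_metadata(replicates: int = 3) -> pd.DataFrame:
    """Sample metadata for the eleven-genotype grapevine design.

    With the default 3 biological replicates per genotype this yields the
    study's classifier group sizes: 21 resistant/partial-resistant vs 12
    susceptible samples.
    """
    rows = [
        (f"{geno}_r{r}", geno, r, group)
        for geno, group in STUDY_GENOTYPES.items()
        for r in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate", "group"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for a synthetic profiling experiment.

    Defaults mirror the grapevine study design: 11 genotypes split 7
    resistant/partial-resistant vs 4 susceptible, 3 biological replicates
    each (21 vs 12 samples), 2000 spectral features of which 190
    discriminate the groups with |log2FC| >= 1.

    Parameters
    ----------
    mz_jitter_ppm : half-width of the uniform per-peak m/z jitter band, in
        ppm; must stay below the downstream alignment tolerance.
    intensity_noise_cv : coefficient of variation of the multiplicative
        log-normal intensity noise (0.3 ~ typical biological plus
        technical variability of direct-infusion profiling).
    log2fc_range : magnitude range for planted group effects; minimum 1 so
        every flagged feature clears the discriminatory fold-change cut.
    """

    n_genotypes_resistant: int = 7
    n_genotypes_susceptible: int = 4
    replicates_per_genotype: int = 3
    n_features: int = 2000
    n_discriminatory: int = 190
    log2fc_range: tuple[float, float] = (1.0, 3.0)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    mz_jitter_ppm: float = 0.3
    missing_rate: float = 0.1
    intensity_noise_cv: float = 0.3
    internal_standard_mz: float = DEFAULT_STANDARD_MZ
    ionization_mode: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genotypes_resistant", "n_genotypes_susceptible",
                     "replicates_per_genotype", "n_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_discriminatory < 0 or self.n_discriminatory > self.n_features:
            raise ValueError("n_discriminatory must lie in [0, n_features]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.log2fc_range[0] < 1 or self.log2fc_range[1] < self.log2fc_range[0]:
            raise ValueError("log2fc_range must be an interval with minimum >= 1")
        if self.mz_jitter_ppm < 0:
            raise ValueError("mz_jitter_ppm must be non-negative")
        if self.intensity_noise_cv < 0:
            raise ValueError("intensity_noise_cv must be non-negative")
        if self.ionization_mode not in MODES:
            raise ValueError(f"ionization_mode must be one of {MODES}")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ValueError("mz_range must be a non-empty interval")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    true_feature_mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    discriminatory_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    true_log2fc: np.ndarray = field(default_factory=lambda: np.empty(0))
    sample_group: dict[str, str] = field(default_factory=dict)
    gene_stability_order: list[str] = field(default_factory=list)
    goi_group_shift: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "true_feature_mz": self.true_feature_mz.tolist(),
            "discriminatory_flags": self.discriminatory_flags.astype(bool).tolist(),
            "true_log2fc": self.true_log2fc.tolist(),
            "sample_group": self.sample_group,
            "gene_stability_order": self.gene_stability_order,
            "goi_group_shift": self.goi_group_shift,
        }


def make_sample_metadata(
    n_resistant: int, n_susceptible: int, replicates: int
) -> pd.DataFrame:
    """Genotype/replicate/group bookkeeping for a two-group design."""
    rows = []
    for g in range(n_resistant):
        for r in range(1, replicates + 1):
            rows.append((f"R{g + 1}_r{r}", f"R{g + 1}", r, RESISTANT))
    for g in range(n_susceptible):
        for r in range(1, replicates + 1):
            rows.append((f"S{g + 1}_r{r}", f"S{g + 1}", r, SUSCEPTIBLE))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate", "group"])


def generate_peak_experiment(
    config: SimulationConfig,
) -> tuple[list[PeakList], pd.DataFrame, GroundTruth]:
    """Simulate per-sample peak lists for a two-group profiling experiment.

    True feature m/z values are laid out on a perturbed grid across
    ``mz_range`` (well separated relative to the jitter band, as real
    metabolite peaks are at FT-ICR resolution).  Each feature has a
    log-normal base abundance; flagged features get a group effect of
    magnitude drawn from ``log2fc_range`` with random sign, applied
    symmetrically (+fc/2 to the resistant mean, -fc/2 to the susceptible
    mean), so true_log2fc is oriented resistant/susceptible.  Every peak
    is observed with probability 1 - missing_rate at m/z jittered
    uniformly within +/- mz_jitter_ppm; the internal standard is present
    in every sample with its own intensity variation.
    """
    rng = np.random.default_rng(config.seed)
    meta = make_sample_metadata(
        config.n_genotypes_resistant,
        config.n_genotypes_susceptible,
        config.replicates_per_genotype,
    )
    n_samples = len(meta)
    is_resistant = (meta["group"] == RESISTANT).to_numpy()

    # true m/z grid with random offsets; keep a guard band away from the
    # internal standard so the standard always forms its own feature
    lo, hi = config.mz_range
    spacing = (hi - lo) / (config.n_features + 1)
    grid = lo + spacing * (np.arange(config.n_features) + 1)
    grid = grid + rng.uniform(-0.2, 0.2, size=config.n_features) * spacing
    std_mz = config.internal_standard_mz
    too_close = np.abs(grid - std_mz) < spacing / 4
    grid[too_close] += spacing / 2
    true_mz = np.sort(grid)

    flags = np.zeros(config.n_features, dtype=bool)
    flags[rng.choice(config.n_features, size=config.n_discriminatory, replace=False)] = True
    log2fc = np.zeros(config.n_features)
    magnitudes = rng.uniform(*config.log2fc_range, size=config.n_discriminatory)
    signs = rng.choice([-1.0, 1.0], size=config.n_discriminatory)
    log2fc[flags] = magnitudes * signs

    # base abundances span ~2.5 decades, as direct-infusion intensities do
    base = 10 ** rng.uniform(4.0, 6.5, size=config.n_features)
    group_mean = np.empty((config.n_features, n_samples))
    group_mean[:, is_resistant] = (base * 2.0 ** (log2fc / 2.0))[:, None]
    group_mean[:, ~is_resistant] = (base * 2.0 ** (-log2fc / 2.0))[:, None]

    sigma = np.sqrt(np.log1p(config.intensity_noise_cv ** 2))
    noise = rng.lognormal(mean=0.0, sigma=sigma, size=group_mean.shape)
    intensities = group_mean * noise

    jitter = rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm,
                         size=group_mean.shape) * 1e-6
    observed_mz = true_mz[:, None] * (1.0 + jitter)

    # detection-limit censoring: missingness concentrates on low-intensity
    # peaks (as in real spectra, where peaks fall below the S/N threshold),
    # with marginal missing fraction ~= missing_rate.  The detection
    # threshold is the missing_rate quantile of all intensities and the
    # per-peak miss probability is logistic in log intensity around it.
    if config.missing_rate > 0:
        log_i = np.log(intensities)
        # bisect the threshold so the expected missing fraction equals
        # missing_rate
        lo, hi = log_i.min() - 10.0, log_i.max() + 10.0
        for _ in range(60):
            mid = (lo + hi) / 2.0
            rate = float(np.mean(1.0 / (1.0 + np.exp((log_i - mid) / 0.5))))
            if rate < config.missing_rate:
                lo = mid
            else:
                hi = mid
        p_miss = 1.0 / (1.0 + np.exp((log_i - (lo + hi) / 2.0) / 0.5))
        present = rng.random(size=group_mean.shape) >= p_miss
    else:
        present = np.ones(group_mean.shape, dtype=bool)

    std_intensity = 1e6 * rng.lognormal(
        mean=0.0, sigma=np.sqrt(np.log1p(0.2 ** 2)), size=n_samples
    )
    std_jitter = rng.uniform(-config.mz_jitter_ppm, config.mz_jitter_ppm,
                             size=n_samples) * 1e-6

    lists = []
    for j, sid in enumerate(meta["sample_id"]):
        keep = present[:, j]
        mz = np.concatenate((observed_mz[keep, j], [std_mz * (1.0 + std_jitter[j])]))
        inten = np.concatenate((intensities[keep, j], [std_intensity[j]]))
        lists.append(PeakList(sample_id=sid, mz=mz, intensity=inten,
                              ionization_mode=config.ionization_mode))

    truth = GroundTruth(
        true_feature_mz=true_mz,
        discriminatory_flags=flags,
        true_log2fc=log2fc,
        sample_group=dict(zip(meta["sample_id"], meta["group"])),
    )
    return lists, meta, truth


def generate_cq_table(
    n_reference_genes: int,
    n_goi: int,
    samples: pd.DataFrame,
    stability_sds: list[float],
    goi_shifts: list[float],
    seed: int = 0,
    sample_effect_sd: float = 0.5,
    goi_noise_sd: float = 0.3,
    efficiencies: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a genes x samples Cq table with graded reference-gene stability.

    Each reference gene's Cq is baseline + shared per-sample effect +
    Gaussian noise with its assigned SD; the shared effect models
    template-amount variation, which stability algorithms should remove.
    Genes of interest additionally receive ``goi_shifts`` (in cycles) in
    the susceptible group — negative shifts mean earlier amplification,
    i.e. higher expression there.

    Returns (cq_table, efficiency_series, ground_truth); reference genes
    are named REF1..n (ordered as ``stability_sds``), genes of interest
    GOI1..n.
    """
    stability_sds = list(stability_sds)
    goi_shifts = list(goi_shifts)
    if len(stability_sds) != n_reference_genes:
        raise ValueError("stability_sds length must equal n_reference_genes")
    if len(goi_shifts) != n_goi:
        raise ValueError("goi_shifts length must equal n_goi")
    if any(sd < 0 for sd in stability_sds):
        raise ValueError("stability SDs must be non-negative")

    rng = np.random.default_rng(seed)
    sample_ids = samples["sample_id"].tolist()
    susceptible = (samples["group"] == SUSCEPTIBLE).to_numpy()
    n_samples = len(sample_ids)

    ref_names = [f"REF{i + 1}" for i in range(n_reference_genes)]
    goi_names = [f"GOI{i + 1}" for i in range(n_goi)]

    sample_effect = rng.normal(0.0, sample_effect_sd, size=n_samples)
    rows = []
    for i, name in enumerate(ref_names):
        baseline = rng.uniform(18.0, 30.0)
        rows.append(baseline + sample_effect
                    + rng.normal(0.0, stability_sds[i], size=n_samples))
    for i, name in enumerate(goi_names):
        baseline = rng.uniform(22.0, 32.0)
        cq = baseline + sample_effect + rng.normal(0.0, goi_noise_sd, size=n_samples)
        cq = cq + goi_shifts[i] * susceptible
        rows.append(cq)

    cq_table = pd.DataFrame(rows, index=ref_names + goi_names, columns=sample_ids)
    cq_table.index.name = "gene"
    if efficiencies is None:
        eff = pd.Series(2.0, index=cq_table.index, name="efficiency")
    else:
        eff = pd.Series(list(efficiencies), index=cq_table.index, name="efficiency")

    order = [ref_names[i] for i in np.argsort(stability_sds, kind="stable")]
    truth = GroundTruth(
        sample_group=dict(zip(samples["sample_id"], samples["group"])),
        gene_stability_order=order,
        goi_group_shift=dict(zip(goi_names, goi_shifts)),
    )
    return cq_table, eff, truth
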