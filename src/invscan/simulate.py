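"""Synthetic SNP datasets with inversion polymorphisms.

The generator emulates the statistical structure the detection pipeline
relies on, at desk scale:

* colinear background: independent biallelic SNPs whose per-location allele
  frequencies are Balding–Nichols draws around a global frequency, giving
  geographic structure controlled by a single F_ST knob;
* inversions: each arrangement carries its own haplotype; a fraction ``d``
  of region SNPs are fixed differences between arrangements (``d`` is the
  single knob for inversion age/divergence), the rest share the background
  frequency. Young-inversion homokaryotypes therefore have reduced region
  heterozygosity and heterokaryotypes elevated heterozygosity;
* karyotypes: two arrangement copies drawn independently from the
  population's arrangement frequencies (Hardy–Weinberg);
* complex regions (three arrangements): the fixed differences are split into
  three equal pattern groups so all arrangements are mutually
  distinguishable, yielding the six-cluster "triforce" PCA geometry;
* missing genotypes: uniform at random (MCAR).

Identical ``SimConfig`` (including seed) gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypeTable, InversionRegion, MapTable, SnpRecord

__all__ = [
    "PopulationSpec",
    "InversionSpec",
    "SimConfig",
    "TruthTable",
    "simulate",
    "expected_heterozygosity",
    "karyotype_label",
]

#: canonical ordering of arrangement symbols within a karyotype label
_ARR_ORDER = {"R": 0, "A": 1, "A1": 2, "A2": 3}


def karyotype_label(copy_a: str, copy_b: str) -> str:
    """Canonical diploid label, e.g. ('A','R') -> 'RA', ('A2','A1') -> 'A1A2'."""
    a, b = sorted((copy_a, copy_b), key=_ARR_ORDER.__getitem__)
    return a + b


@dataclass(frozen=True)
class PopulationSpec:
    location: str
    ecotype: str
    group: str
    n_individuals: int


@dataclass(frozen=True)
class InversionSpec:
    """One simulated inversion region.

    ``freqs`` maps each population index (position in SimConfig.populations)
    to its arrangement-frequency vector (length ``n_arrangements``, sums
    to 1; order R, A or R, A1, A2).
    """

    lg: int
    start_cm: float
    end_cm: float
    n_arrangements: int
    freqs: tuple[tuple[float, ...], ...]
    divergence: float  # fraction of region SNPs fixed between arrangements

    @property
    def arrangements(self) -> tuple[str, ...]:
        return ("R", "A") if self.n_arrangements == 2 else ("R", "A1", "A2")


def _default_populations() -> tuple[PopulationSpec, ...]:
    return (
        PopulationSpec("loc1", "crab", "northern_saxatilis", 20),
        PopulationSpec("loc1", "wave", "northern_saxatilis", 20),
        PopulationSpec("loc2", "crab", "northern_saxatilis", 20),
        PopulationSpec("loc2", "wave", "northern_saxatilis", 20),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small two-location, two-ecotype sample on a single
    30-cM linkage group with one moderately diverged inversion, SNP and
    contig densities in the range of a fragmented linkage map (a handful of
    contigs and a few tens of SNPs per cM), mean background heterozygosity
    0.2, mild geographic structure and 5% missing genotypes.
    """

    n_lg: int = 1
    lg_length_cm: float = 30.0
    snps_per_cm: int = 40
    contigs_per_cm: int = 5
    populations: tuple[PopulationSpec, ...] = field(default_factory=_default_populations)
    inversions: tuple[InversionSpec, ...] = (
        InversionSpec(
            lg=1,
            start_cm=5.0,
            end_cm=15.0,
            n_arrangements=2,
            freqs=((0.5, 0.5), (0.5, 0.5), (0.5, 0.5), (0.5, 0.5)),
            divergence=0.6,
        ),
    )
    background_het: float = 0.2
    fst_between_locations: float = 0.05
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_het < 0.5:
            raise ValueError("background_het must be in (0, 0.5)")
        if not 0 <= self.fst_between_locations < 1:
            raise ValueError("fst_between_locations must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for inv in self.inversions:
            if not inv.start_cm < inv.end_cm <= self.lg_length_cm:
                raise ValueError("inversion must satisfy start_cm < end_cm <= lg_length_cm")
            if inv.n_arrangements not in (2, 3):
                raise ValueError("n_arrangements must be 2 or 3")
            if len(inv.freqs) != len(self.populations):
                raise ValueError("one arrangement-frequency vector per population required")
            for f in inv.freqs:
                if len(f) != inv.n_arrangements:
                    raise ValueError("frequency vector length must equal n_arrangements")
                if abs(sum(f) - 1.0) > 1e-8:
                    raise ValueError("arrangement frequencies must sum to 1")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthTable:
    """Ground truth for parameter-recovery tests.

    karyotypes: individuals x inversions DataFrame of labels (e.g. 'RA');
    regions: the true boundaries; freqs: long DataFrame of the input
    arrangement frequencies per population; divergent_snps: per inversion
    name, indices of region SNPs simulated as fixed differences.
    """

    karyotypes: pd.DataFrame
    regions: list[InversionRegion]
    freqs: pd.DataFrame
    divergent_snps: dict[str, np.ndarray]


def _haplotype_patterns(n_div: int, n_arr: int, rng: np.random.Generator) -> np.ndarray:
    """Fixed-difference allele patterns, shape (n_arr, n_div).

    Two arrangements: R carries 0, A carries 1 at every divergent SNP.
    Three: divergent SNPs split evenly into pattern groups (R|A1A2, A1-only,
    A2-only) so every pair of arrangements differs at ~2/3 of them.
    """
    if n_arr == 2:
        return np.array([[0] * n_div, [1] * n_div], dtype=np.int8)
    pat = np.zeros((3, n_div), dtype=np.int8)
    groups = rng.permutation(n_div) % 3  # 0: R vs both, 1: A1-specific, 2: A2-specific
    pat[1, groups != 2] = 1  # A1 carries alt in groups 0 and 1
    pat[2, groups != 1] = 1  # A2 carries alt in groups 0 and 2
    return pat


def simulate(config: SimConfig) -> tuple[GenotypeTable, pd.DataFrame, MapTable, TruthTable]:
    """Generate (GenotypeTable, SampleMeta, MapTable, TruthTable)."""
    rng = np.random.default_rng(config.seed)

    # --- samples -----------------------------------------------------------
    samples: list[str] = []
    meta_rows = []
    pop_of: list[int] = []  # population index per individual
    for pi, pop in enumerate(config.populations):
        for k in range(pop.n_individuals):
            sid = f"{pop.location}_{pop.ecotype}_{pi}_{k}"
            samples.append(sid)
            meta_rows.append(
                {"individual": sid, "location": pop.location, "ecotype": pop.ecotype, "group": pop.group}
            )
            pop_of.append(pi)
    meta = pd.DataFrame(meta_rows)
    n_ind = len(samples)
    locations = sorted({p.location for p in config.populations})
    loc_idx = {loc: i for i, loc in enumerate(locations)}
    ind_loc = np.array([loc_idx[config.populations[p].location] for p in pop_of])

    # --- map and SNP coordinates ------------------------------------------
    snps: list[SnpRecord] = []
    map_rows = []
    for lg in range(1, config.n_lg + 1):
        n_contigs = int(round(config.contigs_per_cm * config.lg_length_cm))
        contig_cm = (np.arange(n_contigs) + 0.5) / config.contigs_per_cm
        n_snps_lg = int(round(config.snps_per_cm * config.lg_length_cm))
        snp_contig = np.arange(n_snps_lg) % n_contigs  # round-robin over contigs
        for c in range(n_contigs):
            name = f"Contig{lg}_{c}"
            map_rows.append(
                {"contig": name, "lg": lg, "cm_mean": float(contig_cm[c]), "n_markers": 1}
            )
        for j in range(n_snps_lg):
            c = int(snp_contig[j])
            snps.append(
                SnpRecord(
                    snp_id=f"snp{lg}_{j}",
                    contig=f"Contig{lg}_{c}",
                    lg=lg,
                    cm=float(contig_cm[c]),
                    alleles=("A", "T"),
                )
            )
    map_table = MapTable(frame=pd.DataFrame(map_rows))
    n_snps = len(snps)
    snp_lg = np.array([s.lg for s in snps])
    snp_cm = np.array([s.cm for s in snps])

    # --- background allele frequencies -------------------------------------
    theta = config.background_het
    alpha = theta / (1.0 - 2.0 * theta)  # Beta(a,a) global freqs give E[2p(1-p)] = theta
    p_global = rng.beta(alpha, alpha, size=n_snps)
    fst = config.fst_between_locations
    if fst > 0:
        nu = (1.0 - fst) / fst
        p_loc = rng.beta(
            np.maximum(p_global * nu, 1e-12),
            np.maximum((1.0 - p_global) * nu, 1e-12),
            size=(len(locations), n_snps),
        )
    else:
        p_loc = np.broadcast_to(p_global, (len(locations), n_snps)).copy()

    # --- genotypes: colinear draw everywhere, regions overwritten below ----
    geno = rng.binomial(2, p_loc[ind_loc, :]).astype(np.int8)

    # --- inversions ---------------------------------------------------------
    regions: list[InversionRegion] = []
    karyo_cols: dict[str, list[str]] = {}
    freq_rows = []
    divergent: dict[str, np.ndarray] = {}
    counter: dict[int, int] = {}
    for inv in config.inversions:
        counter[inv.lg] = counter.get(inv.lg, 0) + 1
        name = f"LGC{inv.lg}.{counter[inv.lg]}"
        regions.append(
            InversionRegion(name, inv.lg, inv.start_cm, inv.end_cm, inv.n_arrangements == 3)
        )
        in_region = np.flatnonzero(
            (snp_lg == inv.lg) & (snp_cm >= inv.start_cm) & (snp_cm <= inv.end_cm)
        )
        n_div = int(round(inv.divergence * len(in_region)))
        div_idx = rng.choice(in_region, size=n_div, replace=False) if n_div else np.array([], int)
        div_idx = np.sort(div_idx)
        divergent[name] = div_idx
        patterns = _haplotype_patterns(n_div, inv.n_arrangements, rng)

        arrs = inv.arrangements
        copy_a = np.empty(n_ind, dtype=int)
        copy_b = np.empty(n_ind, dtype=int)
        for pi, pop in enumerate(config.populations):
            sel = np.flatnonzero(np.array(pop_of) == pi)
            f = np.asarray(inv.freqs[pi], dtype=float)
            copy_a[sel] = rng.choice(len(arrs), size=len(sel), p=f)
            copy_b[sel] = rng.choice(len(arrs), size=len(sel), p=f)
            for ai, arr in enumerate(arrs):
                freq_rows.append(
                    {
                        "region": name,
                        "location": pop.location,
                        "ecotype": pop.ecotype,
                        "arrangement": arr,
                        "freq": float(f[ai]),
                    }
                )
        karyo_cols[name] = [karyotype_label(arrs[a], arrs[b]) for a, b in zip(copy_a, copy_b)]
        if n_div:
            geno[:, div_idx] = patterns[copy_a, :] + patterns[copy_b, :]

    # --- missingness --------------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    table = GenotypeTable(samples=samples, snps=snps, genotypes=geno)
    truth = TruthTable(
        karyotypes=pd.DataFrame(karyo_cols, index=samples),
        regions=regions,
        freqs=pd.DataFrame(freq_rows),
        divergent_snps=divergent,
    )
    return table, meta, map_table, truth


def expected_heterozygosity(
    karyotype: str, d: float, theta: float, n_arrangements: int = 2
) -> float:
    """Closed-form expected per-SNP heterozygosity inside a simulated region.

    Under the generator's model a region SNP is either a fixed difference
    (fraction ``d``; heterozygous iff the two carried arrangements differ
    there) or a background SNP (heterozygous with probability ``theta``,
    the effective background heterozygosity at the sampling location).
    For two arrangements heterokaryotypes differ at every fixed difference;
    for three, each pair of arrangements differs at 2/3 of them.

    >>> expected_heterozygosity("RA", 1.0, 0.2)
    1.0
    """
    if not 0 <= d <= 1:
        raise ValueError("d must be in [0, 1]")
    # parse the label into its two arrangement symbols
    for split in (1, 2):
        a, b = karyotype[:split], karyotype[split:]
        if a in _ARR_ORDER and b in _ARR_ORDER:
            break
    else:  # pragma: no cover
        raise ValueError(f"unparseable karyotype label: {karyotype}")
    if a == b:
        d_pair = 0.0
    elif n_arrangements == 2:
        d_pair = d
    else:
        d_pair = 2.0 * d / 3.0
    return d_pair * 1.0 + (d - d_pair) * 0.0 + (1.0 - d) * theta


def effective_background_het(config: SimConfig) -> float:
    """Within-location expected heterozygosity: theta reduced by drift, theta*(1-Fst)."""
    return config.background_het * (1.0 - config.fst_between_locations)
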