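"""Synthetic paired tumor/normal studies with planted, recoverable effects.

The generator emulates the data structure the analysis assumes, for a
cohort patterned on a population-based colorectal-cancer case series
(217 tumor/normal pairs, mean age 64.8 (SD 10.1) years, 54.4% male, 13.4%
MSI tumors):

* mRNA counts are negative binomial around ``exp(subject intercept +
  tissue effect) * total/1e6`` with a log-normal subject intercept shared
  by each subject's tumor and normal samples and the sample's total
  protein-coding count as exposure;
* miRNA signals are log-normal with a shared subject intercept, a planted
  tumor effect, and a per-array multiplicative scale artifact for the
  75th-percentile normalization to remove;
* planted miRNA->mRNA effects act on subject-level paired differences:
  the gene's (tumor - normal) RPMPCG equals ``beta * (tumor - normal miRNA
  signal) + age/sex terms + Gaussian noise`` around its own fold-change
  shift, mirroring the fitted association model (counts for these genes
  are Poisson so the linear structure is not drowned by overdispersion);
* 3'UTRs are uniform-random DNA carrying an exact, known number of planted
  seed-complementary sites and no accidental sites for any study miRNA
  (background is rejection-sampled), so seed scans are exactly checkable.

Everything is drawn from one seeded generator: identical config and seed
give bit-identical studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError
from .io import PairedStudy
from .seeds import extract_seeds, seed_site

_DNA = np.array(list("ACGT"))
_RNA = "ACGU"


def gene_name(i: int) -> str:
    return f"GENE{i + 1:04d}"


def mirna_name(i: int) -> str:
    return f"mir-{i + 1:04d}"


@dataclass
class SyntheticConfig:
    """Study-design and effect-size parameters of the generator.

    Planted maps are keyed by the generated names (``GENE0001``...,
    ``mir-0001``...). Effects default to the cohort the generator emulates;
    dispersion and variance components are free parameters of the
    simulation, not estimates of any real dataset.
    """

    n_subjects: int = 217
    n_genes: int = 40
    n_mirnas: int = 30
    frac_msi: float = 0.134
    frac_male: float = 0.544
    frac_colon: float = 0.779
    nb_dispersion: float = 0.05
    baseline_log_mean_range: tuple[float, float] = (0.0, 6.0)
    mirna_baseline_log_range: tuple[float, float] = (2.0, 5.5)
    planted_gene_log_fc: dict[str, float] = field(default_factory=dict)
    planted_mirna_log_fc: dict[str, float] = field(default_factory=dict)
    planted_subgroup_log_fc: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_assoc: list[tuple[str, str, float]] = field(default_factory=list)
    planted_seed_sites: dict[tuple[str, str], int] = field(default_factory=dict)
    age_distribution: tuple[float, float] = (64.8, 10.1)
    subject_sd: float = 0.3
    mirna_subject_sd: float = 0.3
    mirna_noise_sd: float = 0.3
    array_scale_sd: float = 0.2
    assoc_noise_sd: float = 10.0
    assoc_age_coef: float = 0.2
    assoc_sex_coef: float = 5.0
    #: subject-intercept spread for genes carrying a planted association.
    #: Tighter than subject_sd so the additive difference-scale model stays
    #: clear of the positivity floor (censoring there would attenuate the
    #: planted slope instead of merely adding noise).
    assoc_subject_sd: float = 0.15
    #: log RPMPCG baseline for genes carrying a planted association; such a
    #: gene needs expression on a scale commensurate with beta * miRNA diff,
    #: otherwise the positivity floor of the tumor mean censors the planted
    #: linear effect. None: sample from baseline_log_mean_range like any gene.
    assoc_gene_log_baseline: float | None = np.log(300.0)
    #: log signal baseline for miRNAs carrying a planted association, for the
    #: same reason: the planted slope is detectable only when the miRNA's
    #: paired-difference spread is commensurate with the gene's noise.
    assoc_mirna_log_baseline: float | None = np.log(150.0)
    total_pc_mean: float = 2.0e7
    total_pc_log_sd: float = 0.15
    utr_length: int = 1000
    mature_length: int = 22
    seed: int = 0

    def gene_ids(self) -> list[str]:
        return [gene_name(i) for i in range(self.n_genes)]

    def mirna_ids(self) -> list[str]:
        return [mirna_name(i) for i in range(self.n_mirnas)]

    def validate(self) -> "SyntheticConfig":
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be at least 2")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not 0 <= self.frac_msi <= 1:
            raise ConfigurationError("frac_msi must lie in [0, 1]")
        if self.utr_length < 8:
            raise ConfigurationError("utr_length must be at least 8")
        genes = set(self.gene_ids())
        mirnas = set(self.mirna_ids())
        for g in self.planted_gene_log_fc:
            if g not in genes:
                raise ConfigurationError(f"planted_gene_log_fc names unknown gene {g}")
        for m in self.planted_mirna_log_fc:
            if m not in mirnas:
                raise ConfigurationError(f"planted_mirna_log_fc names unknown miRNA {m}")
        for (g, sub) in self.planted_subgroup_log_fc:
            if g not in genes or sub not in ("MSI", "MSS"):
                raise ConfigurationError(
                    f"planted_subgroup_log_fc has invalid key {(g, sub)}")
        for (g, m, _beta) in self.planted_assoc:
            if g not in genes or m not in mirnas:
                raise ConfigurationError(f"planted_assoc names unknown pair {(g, m)}")
        for (g, m), count in self.planted_seed_sites.items():
            if g not in genes or m not in mirnas:
                raise ConfigurationError(f"planted_seed_sites names unknown pair {(g, m)}")
            if count < 0:
                raise ConfigurationError("planted_seed_sites counts must be >= 0")
        return self


@dataclass
class GroundTruth:
    """Planted effects, for parameter-recovery tests.

    ``true_fc`` is the expected tumor/normal ratio of mean RPMPCG implied
    by all planted effects (tissue effect, subgroup mixture, and the mean
    shift contributed by planted miRNA associations).
    """

    true_fc: dict[str, float]
    true_beta: dict[tuple[str, str], float]
    true_seed_sites: dict[tuple[str, str], list[int]]
    subgroup_effects: dict[tuple[str, str], float]


@dataclass
class SyntheticStudy:
    """Everything the generator produces for one configuration."""

    study: PairedStudy
    truth: GroundTruth
    utrs: dict[str, str]
    mature_seqs: dict[str, str]


def _random_dna(length: int, rng) -> np.ndarray:
    return _DNA[rng.integers(0, 4, size=length)]


def _find_all(haystack: str, needle: str) -> list[int]:
    out = []
    pos = haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def _plant_multi(length: int, plants: list[tuple[str, str, int]],
                 forbidden: dict[str, str], rng) -> tuple[str, dict[str, list[int]]]:
    """Build a DNA string with exact planted site counts and no strays.

    ``plants``: (key, site, count) triples; ``forbidden``: key -> site that
    must not occur outside planted intervals. Returns the sequence and the
    planted positions per key.
    """
    total_len = sum(len(site) * count for _k, site, count in plants)
    if total_len > length:
        raise CapacityError(
            f"cannot pack {total_len} site bases into a {length}-base UTR")
    seq = _random_dna(length, rng)
    intervals: list[tuple[int, int]] = []
    positions: dict[str, list[int]] = {k: [] for k, _s, _c in plants}
    for key, site, count in plants:
        w = len(site)
        for _ in range(count):
            for _try in range(10_000):
                pos = int(rng.integers(0, length - w + 1))
                if all(pos + w <= a or pos >= b for a, b in intervals):
                    break
            else:
                raise CapacityError("could not place non-overlapping seed sites")
            intervals.append((pos, pos + w))
            seq[pos:pos + w] = list(site)
            positions[key].append(pos)
    planted_by_key = {k: set(v) for k, v in positions.items()}

    watch = {k: s for k, s, _c in plants}
    watch.update(forbidden)
    for _round in range(2_000):
        dirty = False
        text = "".join(seq)
        for key, site in watch.items():
            ok = planted_by_key.get(key, set())
            for pos in _find_all(text, site):
                if pos in ok and key in planted_by_key:
                    continue
                free = [i for i in range(pos, pos + len(site))
                        if all(i < a or i >= b for a, b in intervals)]
                if not free:
                    # the occurrence lies wholly inside planted material:
                    # fine for a forbidden-only watch (it is part of a site
                    # deliberately planted there), unfixable for a planted key
                    if key in planted_by_key:
                        raise CapacityError(
                            "planted sites overlap into an extra occurrence; "
                            "regenerate with a different rng state")
                    continue
                i = int(rng.choice(free))
                choices = [b for b in "ACGT" if b != seq[i]]
                seq[i] = choices[int(rng.integers(0, 3))]
                dirty = True
        if not dirty:
            break
    else:
        raise CapacityError("rejection sampling of UTR background did not settle")
    for k in positions:
        positions[k] = sorted(positions[k])
    return "".join(seq), positions


def plant_seed_sites(utr_length: int, seed_rna: str, n_sites: int, rng) -> str:
    """A random UTR containing exactly ``n_sites`` sites for one seed.

    The returned DNA sequence contains exactly ``n_sites`` non-overlapping
    occurrences of the DNA reverse complement of ``seed_rna`` and no other
    occurrence anywhere (the background is rejection-sampled).
    """
    if len(seed_rna) not in (6, 7, 8):
        raise ConfigurationError("seed length must be 6, 7 or 8")
    if n_sites < 0:
        raise ConfigurationError("n_sites must be >= 0")
    if n_sites * len(seed_rna) > utr_length:
        raise CapacityError(
            f"{n_sites} sites of length {len(seed_rna)} exceed UTR length {utr_length}")
    site = seed_site(seed_rna)
    seq, _pos = _plant_multi(utr_length, [("seed", site, n_sites)], {}, rng)
    return seq


def _mixture_fc(log_fc: float, sub_effects: dict[str, float], frac_msi: float) -> float:
    """Expected mean-ratio fold change under the MSI/MSS mixture."""
    f_msi = np.exp(log_fc + sub_effects.get("MSI", 0.0))
    f_mss = np.exp(log_fc + sub_effects.get("MSS", 0.0))
    return float(frac_msi * f_msi + (1 - frac_msi) * f_mss)


def generate_all(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full synthetic study, its ground truth, and sequences."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    mirnas = config.mirna_ids()
    n = config.n_subjects

    # --- subjects and samples -------------------------------------------
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    age_mean, age_sd = config.age_distribution
    ages = np.clip(rng.normal(age_mean, age_sd, size=n), 30, 79).round(1)
    sexes = np.where(rng.random(n) < config.frac_male, "M", "F")
    sites = np.where(rng.random(n) < config.frac_colon, "colon", "rectal")
    msi = np.where(rng.random(n) < config.frac_msi, "MSI", "MSS")
    subjects = pd.DataFrame(
        {"age": ages, "sex": sexes, "site": sites, "msi_status": msi},
        index=pd.Index(subject_ids, name="subject"),
    )
    tumor_samples = [f"{s}_T" for s in subject_ids]
    normal_samples = [f"{s}_N" for s in subject_ids]
    samples = [x for pair in zip(tumor_samples, normal_samples) for x in pair]
    sample_map = pd.DataFrame(
        {
            "subject": [s for s in subject_ids for _ in range(2)],
            "tissue": ["tumor", "normal"] * n,
        },
        index=pd.Index(samples, name="sample"),
    )
    totals = pd.Series(
        np.round(rng.lognormal(np.log(config.total_pc_mean),
                               config.total_pc_log_sd, size=2 * n)).astype(np.int64),
        index=sample_map.index,
    )

    # --- miRNA signals ---------------------------------------------------
    v = rng.uniform(*config.mirna_baseline_log_range, size=len(mirnas))
    if config.assoc_mirna_log_baseline is not None:
        assoc_mirs = {m for _g, m, _b in config.planted_assoc}
        for mi, m in enumerate(mirnas):
            if m in assoc_mirs:
                v[mi] = config.assoc_mirna_log_baseline
    g_mir = np.array([config.planted_mirna_log_fc.get(m, 0.0) for m in mirnas])
    b_mir = rng.normal(0.0, config.mirna_subject_sd, size=(len(mirnas), n))
    eps_t = rng.normal(0.0, config.mirna_noise_sd, size=(len(mirnas), n))
    eps_n = rng.normal(0.0, config.mirna_noise_sd, size=(len(mirnas), n))
    true_t = np.exp(v[:, None] + b_mir + g_mir[:, None] + eps_t)
    true_n = np.exp(v[:, None] + b_mir + eps_n)
    true_diff = true_t - true_n  # the planted predictor
    scale = rng.lognormal(0.0, config.array_scale_sd, size=2 * n)
    observed = np.empty((len(mirnas), 2 * n))
    observed[:, 0::2] = true_t
    observed[:, 1::2] = true_n
    observed *= scale[None, :]
    mirna_signals = pd.DataFrame(observed, index=pd.Index(mirnas, name="mirna"),
                                 columns=sample_map.index)

    # expected value of each miRNA's paired difference (for true_fc bookkeeping)
    mean_x = (np.exp(v + config.mirna_subject_sd ** 2 / 2)
              * (np.exp(g_mir) - 1.0) * np.exp(config.mirna_noise_sd ** 2 / 2))
    mean_x_by_mirna = dict(zip(mirnas, mean_x))

    # --- mRNA counts -----------------------------------------------------
    assoc_by_gene: dict[str, list[tuple[str, float]]] = {}
    for g, m, beta in config.planted_assoc:
        assoc_by_gene.setdefault(g, []).append((m, beta))
    mirna_index = {m: i for i, m in enumerate(mirnas)}

    u = rng.uniform(*config.baseline_log_mean_range, size=len(genes))
    if config.assoc_gene_log_baseline is not None:
        for gi, g in enumerate(genes):
            if g in assoc_by_gene:
                u[gi] = config.assoc_gene_log_baseline
    t_tumor = totals[tumor_samples].to_numpy(float)
    t_normal = totals[normal_samples].to_numpy(float)
    sex_ind = (sexes == "M").astype(float)
    alpha = config.nb_dispersion
    counts = np.zeros((len(genes), 2 * n), dtype=np.int64)
    true_fc: dict[str, float] = {}
    sub_effects_out: dict[tuple[str, str], float] = {}

    def nb_draw(mu):
        if alpha < 1e-12:
            return rng.poisson(mu)
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
        return rng.poisson(lam)

    for gi, g in enumerate(genes):
        f = config.planted_gene_log_fc.get(g, 0.0)
        subs = {s: e for (gg, s), e in config.planted_subgroup_log_fc.items() if gg == g}
        for s, e in subs.items():
            sub_effects_out[(g, s)] = e
        f_per_subject = f + np.array([subs.get(st, 0.0) for st in msi])
        subj_sd = config.assoc_subject_sd if g in assoc_by_gene else config.subject_sd
        a = rng.normal(0.0, subj_sd, size=n)
        r_normal = np.exp(u[gi] + a)  # RPMPCG scale
        if g in assoc_by_gene:
            # additive structural model on the RPMPCG difference scale:
            # diff_i = base*(FC-1) + beta * miRNA_diff_i + age/sex terms + noise,
            # exactly the linear model the association stage fits
            d = rng.normal(0.0, config.assoc_noise_sd, size=n)
            d += config.assoc_age_coef * (ages - age_mean)
            d += config.assoc_sex_coef * (sex_ind - config.frac_male)
            mean_shift = 0.0
            for m, beta in assoc_by_gene[g]:
                d += beta * true_diff[mirna_index[m]]
                mean_shift += beta * mean_x_by_mirna[m]
            base = np.exp(u[gi])
            tissue_shift = base * (np.exp(f_per_subject) - 1.0)
            r_tumor = np.maximum(r_normal + tissue_shift + d, 0.01 * r_normal)
            counts[gi, 0::2] = rng.poisson(r_tumor * t_tumor / 1e6)
            counts[gi, 1::2] = rng.poisson(r_normal * t_normal / 1e6)
            mean_normal = base * np.exp(subj_sd ** 2 / 2)
            true_fc[g] = 1.0 + (
                base * (_mixture_fc(f, subs, config.frac_msi) - 1.0) + mean_shift
            ) / mean_normal
        else:
            mu_t = r_normal * np.exp(f_per_subject) * t_tumor / 1e6
            mu_n = r_normal * t_normal / 1e6
            counts[gi, 0::2] = nb_draw(mu_t)
            counts[gi, 1::2] = nb_draw(mu_n)
            true_fc[g] = _mixture_fc(f, subs, config.frac_msi)
    mrna_counts = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                               columns=sample_map.index)

    # --- sequences -------------------------------------------------------
    rna = np.array(list(_RNA))
    mature_seqs = {
        m: "".join(rna[rng.integers(0, 4, size=config.mature_length)])
        for m in mirnas
    }
    # 6-mer sites of every study miRNA are kept out of every UTR background;
    # any stray 7/8-mer site necessarily contains a 6-mer site, so this is
    # enough to keep backgrounds free of matches at all three lengths
    forbidden = {
        f"{m}/6": seed_site(next(s for L, s, _p in extract_seeds(m, seq).seeds if L == 6))
        for m, seq in mature_seqs.items()
    }
    sites_by_gene: dict[str, list[tuple[str, str, int]]] = {}
    for (g, m), count in config.planted_seed_sites.items():
        seed8 = next(s for L, s, _p in extract_seeds(m, mature_seqs[m]).seeds if L == 8)
        sites_by_gene.setdefault(g, []).append((m, seed_site(seed8), count))
    utrs: dict[str, str] = {}
    true_seed_sites: dict[tuple[str, str], list[int]] = {}
    for g in genes:
        plants = sites_by_gene.get(g, [])
        seq, positions = _plant_multi(config.utr_length, plants, forbidden, rng)
        utrs[g] = seq
        for m, pos_list in positions.items():
            true_seed_sites[(g, m)] = pos_list

    study = PairedStudy(
        subjects=subjects,
        mrna_counts=mrna_counts,
        mirna_signals=mirna_signals,
        sample_map=sample_map,
        total_pc_counts=totals,
    ).validate()
    truth = GroundTruth(
        true_fc=true_fc,
        true_beta={(g, m): b for g, m, b in config.planted_assoc},
        true_seed_sites=true_seed_sites,
        subgroup_effects=sub_effects_out,
    )
    return SyntheticStudy(study=study, truth=truth, utrs=utrs,
                          mature_seqs=mature_seqs)


def benchmark_config(n_subjects: int = 200, seed: int = 0) -> SyntheticConfig:
    """The canonical parameter-recovery benchmark configuration.

    Twenty dysregulated genes and 150 miRNAs of which 30 are dysregulated
    (so the association screen crosses 20 x 30 pairs), with five planted
    associations of |beta| >= 0.3. The three negative-slope pairs follow
    the direct-repression pattern — miRNA upregulated (FC 1.8), target
    downregulated (FC 0.60), seed sites planted in the target's UTR — and
    the two positive-slope pairs are upregulated genes driven by
    upregulated miRNAs with no seed site. Effect sizes are moderate by
    design: planted slopes are only identifiable when the additive
    difference-scale model stays clear of the count positivity floor.
    """
    rng = np.random.default_rng(99)  # fixed: the design, not the data
    genes = [gene_name(i) for i in range(20)]
    mirnas = [mirna_name(i) for i in range(150)]
    assoc = [(genes[0], mirnas[0], -0.35), (genes[1], mirnas[2], -0.30),
             (genes[2], mirnas[4], -0.40), (genes[3], mirnas[6], 0.35),
             (genes[4], mirnas[8], 0.30)]
    gene_fc = {g: (np.log(1.7) if i % 2 == 0 else np.log(0.60))
               for i, g in enumerate(genes)}
    for g, _m, b in assoc:
        gene_fc[g] = np.log(0.60) if b < 0 else np.log(1.7)
    mirna_fc = {}
    for i in range(30):
        mag = rng.uniform(np.log(1.8), np.log(3.0))
        mirna_fc[mirnas[i]] = mag if i % 2 == 0 else -mag
    for _g, m, _b in assoc:
        mirna_fc[m] = np.log(1.8)
    seed_sites = {(genes[0], mirnas[0]): 1, (genes[1], mirnas[2]): 2,
                  (genes[2], mirnas[4]): 1}
    return SyntheticConfig(
        n_subjects=n_subjects, n_genes=20, n_mirnas=150, seed=seed,
        planted_gene_log_fc=gene_fc, planted_mirna_log_fc=mirna_fc,
        planted_assoc=assoc, planted_seed_sites=seed_sites,
        mirna_baseline_log_range=(3.0, 5.5),
    )


def generate_study(config: SyntheticConfig) -> tuple[PairedStudy, GroundTruth]:
    """Generate a paired study and its ground truth (see :func:`generate_all`)."""
    out = generate_all(config)
    return out.study, out.truth


def write_bundle(config: SyntheticConfig, bundle_path) -> SyntheticStudy:
    """Generate a study and write the full bundle (TSVs, FASTAs, truth JSON)."""
    import json
    from pathlib import Path

    from .io import write_study

    out = generate_all(config)
    bundle = Path(bundle_path)
    write_study(out.study, bundle, utrs=out.utrs, mirna_seqs=out.mature_seqs)
    truth = {
        "true_fc": out.truth.true_fc,
        "true_beta": {f"{g}\t{m}": b for (g, m), b in out.truth.true_beta.items()},
        "true_seed_sites": {f"{g}\t{m}": p
                            for (g, m), p in out.truth.true_seed_sites.items()},
        "subgroup_effects": {f"{g}\t{s}": e
                             for (g, s), e in out.truth.subgroup_effects.items()},
    }
    (bundle / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out
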