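"""Synthetic divergent-selection cohort: pedigree, genotypes, traits.

The generator emulates a small selective-mating design — a handful of sires
with extreme breeding values mated within "short" (ST) and "long" (LT) groups,
their lamb crop, and a set of ungenotyped herd contemporaries — so every
downstream stage (QC, kinship, REML, GWAS, annotation) can be exercised
without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .data import UNKNOWN_PARENT, GenotypeMatrix, Pedigree

__all__ = [
    "TraitSpec",
    "CohortConfig",
    "TrueParams",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_traits",
    "default_trait_panel",
]


class ConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass
class TraitSpec:
    """Target architecture of one simulated trait.

    ``h2``/``d2`` are the additive and dominance fractions of phenotypic
    variance; for binary traits they apply to the latent liability and
    ``prevalence`` fixes the threshold.
    """

    name: str
    kind: str = "gaussian"  # gaussian | count | binary
    h2: float = 0.5
    d2: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "count", "binary"):
            raise ConfigError(f"unknown trait kind {self.kind!r}")
        if not (0.0 <= self.h2 <= 1.0) or not (0.0 <= self.d2 <= 1.0):
            raise ConfigError(f"{self.name}: h2/d2 must be in [0,1]")
        if self.h2 + self.d2 > 1.0:
            raise ConfigError(f"{self.name}: h2 + d2 exceeds 1")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ConfigError(f"{self.name}: binary trait needs prevalence in (0,1)")
        if self.sd <= 0:
            raise ConfigError(f"{self.name}: sd must be positive")


def default_trait_panel() -> list[TraitSpec]:
    """Trait panel mirroring a tail/body-measurement recording scheme.

    Four Gaussian measurements, one vertebra count, and four binary
    malformation indicators with prevalences 15.28%, 12.89%, 8.33%, 27.73%.
    """
    return [
        TraitSpec("TL", "gaussian", h2=0.80, d2=0.15, mean=22.5, sd=2.3),
        TraitSpec("TC", "gaussian", h2=0.21, d2=0.0, mean=6.5, sd=0.5),
        TraitSpec("BL", "gaussian", h2=0.85, d2=0.0, mean=32.7, sd=2.4),
        TraitSpec("BW", "gaussian", h2=0.85, d2=0.0, mean=5.4, sd=0.95),
        TraitSpec("nVERT", "count", h2=0.29, d2=0.0, mean=20.35, sd=1.63),
        TraitSpec("AXISD", "binary", h2=0.20, d2=0.0, prevalence=0.1528),
        TraitSpec("BLCKV", "binary", h2=0.20, d2=0.0, prevalence=0.1289),
        TraitSpec("WDGV", "binary", h2=0.20, d2=0.0, prevalence=0.0833),
        TraitSpec("FRC", "binary", h2=0.20, d2=0.0, prevalence=0.2773),
    ]


@dataclass
class CohortConfig:
    """Knobs of the simulated selection/mating experiment."""

    n_sires: int = 4
    n_ewes: int = 142
    n_lambs: int = 254
    n_contemporaries_ungenotyped: int = 38
    lambs_per_sire: Optional[list[int]] = None
    n_variants: int = 2000
    n_chromosomes: int = 26
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl_additive: int = 200
    n_qtl_dominance: int = 100
    traits: list[TraitSpec] = field(default_factory=default_trait_panel)
    trait_effect_corr: Optional[float] = None
    selection_differential: float = 1.0
    crossovers_per_chromosome: float = 1.0
    n_demes: int = 1
    deme_divergence: float = 0.0
    missing_rate: float = 0.0
    fixed_effect_scale: float = 0.25  # in units of phenotypic SD, <= 0.5
    dominance_degree_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambs_per_sire is None:
            if (self.n_sires, self.n_lambs) == (4, 254):
                self.lambs_per_sire = [62, 65, 64, 63]
            else:
                base, extra = divmod(self.n_lambs, max(self.n_sires, 1))
                self.lambs_per_sire = [
                    base + (1 if i < extra else 0) for i in range(self.n_sires)
                ]
        if len(self.lambs_per_sire) != self.n_sires:
            raise ConfigError("lambs_per_sire length must equal n_sires")
        if sum(self.lambs_per_sire) != self.n_lambs:
            raise ConfigError(
                f"lambs_per_sire sums to {sum(self.lambs_per_sire)}, "
                f"expected n_lambs={self.n_lambs}"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        if self.n_variants < self.n_qtl_additive:
            raise ConfigError("n_variants < n_qtl_additive")
        if self.n_qtl_dominance > self.n_qtl_additive:
            raise ConfigError("n_qtl_dominance cannot exceed n_qtl_additive")
        if self.n_lambs > 0 and self.n_ewes == 0:
            raise ConfigError("lambs require ewes")
        if self.n_lambs > 3 * self.n_ewes:
            raise ConfigError("more lambs than ewes can bear (max litter 3)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0,1)")
        for t in self.traits:
            if t.kind == "binary" and not (0 < t.prevalence < 1):
                raise ConfigError("prevalence must be in (0,1)")


@dataclass
class TrueParams:
    """Ground truth of a simulated trait panel, for recovery tests."""

    seed: int
    variance_components: dict  # trait -> {"sigma_g2","sigma_d2","sigma_e2"}
    qtl_index: np.ndarray
    qtl_additive_effects: dict  # trait -> array over QTLs (scaled)
    qtl_dominance_effects: dict
    breeding_values: pd.DataFrame  # animal x trait
    dominance_deviations: pd.DataFrame

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "variance_components": self.variance_components,
            "qtl_index": self.qtl_index.tolist(),
            "qtl_additive_effects": {
                k: v.tolist() for k, v in self.qtl_additive_effects.items()
            },
            "qtl_dominance_effects": {
                k: v.tolist() for k, v in self.qtl_dominance_effects.items()
            },
            "breeding_values": self.breeding_values.to_dict(orient="list"),
            "dominance_deviations": self.dominance_deviations.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: CohortConfig) -> Pedigree:
    """Build the mating-experiment pedigree.

    Founder sires are split into an ST (low-EBV) and an LT (high-EBV) half;
    ewes are assigned to sires within group; lambs carry litter size
    (birth type), dam parity, and sex as covariates. Ungenotyped herd
    contemporaries descend from separate founder matings.
    """
    rng = np.random.default_rng(config.seed)
    rows = []

    sires = [f"SIRE{i + 1}" for i in range(config.n_sires)]
    n_st = config.n_sires // 2
    sire_group = {
        s: ("ST" if i < n_st else "LT") for i, s in enumerate(sires)
    }
    for s in sires:
        rows.append(
            dict(
                animal=s, sire=UNKNOWN_PARENT, dam=UNKNOWN_PARENT, birth_year=2019,
                sex="male", group=sire_group[s], birth_type=1, parity=1,
                genotyped=True, role="founder",
            )
        )

    ewes = [f"EWE{i + 1}" for i in range(config.n_ewes)]
    # ewes allotted to sires proportionally to that sire's lamb quota
    quota = np.asarray(config.lambs_per_sire, dtype=float)
    if quota.sum() > 0:
        ewe_counts = np.floor(quota / quota.sum() * config.n_ewes).astype(int)
        while ewe_counts.sum() < config.n_ewes:
            ewe_counts[int(np.argmax(quota - ewe_counts))] += 1
    else:
        ewe_counts = np.full(config.n_sires, config.n_ewes // max(config.n_sires, 1))
    ewe_sire: dict[str, str] = {}
    idx = 0
    for s, cnt in zip(sires, ewe_counts):
        for _ in range(cnt):
            if idx >= len(ewes):
                break
            ewe_sire[ewes[idx]] = s
            idx += 1
    for e in ewes[idx:]:
        ewe_sire[e] = sires[-1] if sires else UNKNOWN_PARENT
    for e in ewes:
        grp = sire_group.get(ewe_sire.get(e, ""), "ST")
        rows.append(
            dict(
                animal=e, sire=UNKNOWN_PARENT, dam=UNKNOWN_PARENT, birth_year=2019,
                sex="female", group=grp, birth_type=1,
                parity=int(rng.integers(1, 5)), genotyped=True, role="founder",
            )
        )

    # lambs: per sire quota, litters of 1-3 assigned to that sire's ewes
    lamb_no = 0
    for s, n_off in zip(sires, config.lambs_per_sire):
        my_ewes = [e for e in ewes if ewe_sire[e] == s]
        if n_off > 0 and not my_ewes:
            raise ConfigError(f"no ewes assigned to sire {s}")
        remaining = n_off
        ewe_cursor = 0
        while remaining > 0:
            if ewe_cursor >= len(my_ewes):
                raise ConfigError(
                    f"sire {s}: lamb quota {n_off} exceeds ewe capacity "
                    f"({len(my_ewes)} ewes, max litter 3)"
                )
            dam = my_ewes[ewe_cursor]
            ewes_left_after = len(my_ewes) - ewe_cursor - 1
            lo = max(1, remaining - 3 * ewes_left_after)  # keep quota feasible
            litter = int(np.clip(rng.integers(1, 4), lo, remaining))
            dam_parity = int(
                next(r["parity"] for r in rows if r["animal"] == dam)
            )
            for _ in range(litter):
                lamb_no += 1
                rows.append(
                    dict(
                        animal=f"LAMB{lamb_no}", sire=s, dam=dam, birth_year=2021,
                        sex="male" if rng.random() < 0.5 else "female",
                        group=sire_group[s], birth_type=litter, parity=dam_parity,
                        genotyped=True, role="lamb",
                    )
                )
            remaining -= litter
            ewe_cursor += 1

    # ungenotyped herd contemporaries from separate founder matings
    if config.n_contemporaries_ungenotyped > 0:
        n_con_sires = max(1, min(2, config.n_contemporaries_ungenotyped))
        con_sires = [f"CSIRE{i + 1}" for i in range(n_con_sires)]
        for cs in con_sires:
            rows.append(
                dict(
                    animal=cs, sire=UNKNOWN_PARENT, dam=UNKNOWN_PARENT,
                    birth_year=2019, sex="male", group="CON", birth_type=1,
                    parity=1, genotyped=False, role="founder",
                )
            )
        n_con_dams = (config.n_contemporaries_ungenotyped + 1) // 2
        con_no = 0
        for d in range(n_con_dams):
            dam = f"CEWE{d + 1}"
            parity = int(rng.integers(1, 5))
            rows.append(
                dict(
                    animal=dam, sire=UNKNOWN_PARENT, dam=UNKNOWN_PARENT,
                    birth_year=2019, sex="female", group="CON", birth_type=1,
                    parity=parity, genotyped=False, role="founder",
                )
            )
            litter = min(2, config.n_contemporaries_ungenotyped - con_no)
            for _ in range(litter):
                con_no += 1
                rows.append(
                    dict(
                        animal=f"CON{con_no}", sire=con_sires[d % n_con_sires],
                        dam=dam, birth_year=2021,
                        sex="male" if rng.random() < 0.5 else "female",
                        group="CON", birth_type=litter, parity=parity,
                        genotyped=False, role="contemporary",
                    )
                )

    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _variant_table(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_variants
    per_chrom = np.full(config.n_chromosomes, m // config.n_chromosomes)
    per_chrom[: m % config.n_chromosomes] += 1
    chroms = np.repeat(
        [str(c + 1) for c in range(config.n_chromosomes)], per_chrom
    )
    pos = np.concatenate([(np.arange(k) + 1) * 1000 for k in per_chrom if k > 0])
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    ref = rng.choice(list("ACGT"), size=m)
    shift = rng.integers(1, 4, size=m)
    bases = np.array(list("ACGT"))
    base_idx = {b: i for i, b in enumerate(bases)}
    alt = bases[(np.vectorize(base_idx.get)(ref) + shift) % 4]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos.astype(int),
            "ref": ref,
            "alt": alt,
            "maf": maf,
        }
    )


def simulate_genotypes(ped: Pedigree, config: CohortConfig) -> GenotypeMatrix:
    """Gene-drop genotypes through the pedigree.

    Founder haplotypes are drawn at the configured MAFs (Hardy–Weinberg);
    offspring gametes are produced by Mendelian transmission with a uniform
    within-chromosome recombination process. Returns dosages for *all*
    pedigree animals (downstream callers subset to genotyped ones).
    """
    rng = np.random.default_rng(config.seed + 1)
    vtab = _variant_table(config, rng)
    m = len(vtab)
    p = vtab["maf"].to_numpy()

    # per-adjacent-variant switch probability; chromosome starts get 0.5 so a
    # cumulative-sum parity trick yields independent chromosomes
    switch = np.empty(m)
    chrom_arr = vtab["chrom"].to_numpy()
    start_of_chrom = np.r_[True, chrom_arr[1:] != chrom_arr[:-1]]
    chrom_sizes = vtab.groupby("chrom", sort=False).size().to_numpy()
    per_variant_rate = np.concatenate(
        [
            np.full(k, config.crossovers_per_chromosome / max(k - 1, 1))
            for k in chrom_sizes
        ]
    )
    switch[:] = np.minimum(per_variant_rate, 0.5)
    switch[start_of_chrom] = 0.5

    order = ped.topological_order()
    parent_map = dict(
        zip(ped.records["animal"], zip(ped.records["sire"], ped.records["dam"]))
    )
    index = {a: i for i, a in enumerate(order)}
    haplos = np.empty((len(order), 2, m), dtype=np.uint8)

    cols = np.arange(m)

    def gamete(parent_row: np.ndarray) -> np.ndarray:
        src = (rng.random(m) < switch).cumsum() % 2
        return parent_row[src, cols]

    # optional population structure: founders split into demes whose variant
    # frequencies diverge symmetrically around the base MAF
    deme_of = {}
    if config.n_demes > 1:
        founders = [a for a in order if parent_map[a][0] == UNKNOWN_PARENT
                    and parent_map[a][1] == UNKNOWN_PARENT]
        for rank, a in enumerate(founders):
            deme_of[a] = rank % config.n_demes
        shifts = np.linspace(-0.5, 0.5, config.n_demes) * config.deme_divergence
        deme_freqs = [np.clip(p + s, 0.01, 0.99) for s in shifts]

    for a in order:
        sire, dam = parent_map[a]
        i = index[a]
        pf = deme_freqs[deme_of[a]] if a in deme_of else p
        for h, par in enumerate((sire, dam)):
            if par == UNKNOWN_PARENT or par not in index:
                haplos[i, h] = rng.random(m) < pf
            else:
                haplos[i, h] = gamete(haplos[index[par]])

    dosages = haplos.sum(axis=1).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    # restore pedigree record order
    rows = np.array([index[a] for a in ped.animals])
    dosages = dosages[rows]
    variants = vtab.drop(columns=["maf"]).copy()
    geno = GenotypeMatrix(dosages=dosages, variants=variants, samples=ped.animals)
    geno.variants["af"] = geno.allele_freq()
    return geno


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def _scaled(values: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    v = float(np.var(values))
    if target_var <= 0 or v <= 0:
        return np.zeros_like(values), 0.0
    f = np.sqrt(target_var / v)
    return values * f, f


def simulate_traits(
    ped: Pedigree, geno: GenotypeMatrix, config: CohortConfig
) -> tuple[pd.DataFrame, TrueParams]:
    """Phenotype every pedigree animal from QTL effects plus noise.

    Continuous traits: mean + sex/birth-type/parity effects + additive QTL
    values + dominance deviations + Gaussian residual, rescaled so realized
    h2 and d2 equal the targets on the cohort. The count trait rounds a
    latent Gaussian; binary traits threshold a liability at the quantile
    implied by the configured prevalence.
    """
    rng = np.random.default_rng(config.seed + 2)
    missing_from_geno = set(ped.animals) - set(geno.samples)
    if missing_from_geno:
        raise ConfigError(
            "genotypes must cover all pedigree animals for trait simulation; "
            f"missing e.g. {sorted(missing_from_geno)[:3]}"
        )
    g = geno.subset_samples(ped.animals)
    x = g.imputed_dosages()
    n = x.shape[0]
    p = g.allele_freq()

    qtl = rng.choice(g.n_variants, size=config.n_qtl_additive, replace=False)
    qtl.sort()
    dom_qtl_mask = np.zeros(config.n_qtl_additive, dtype=bool)
    dom_qtl_mask[
        rng.choice(config.n_qtl_additive, size=config.n_qtl_dominance, replace=False)
    ] = True

    xa = x[:, qtl] - 2.0 * p[qtl]  # centred additive coding
    pq, qq = p[qtl], 1.0 - p[qtl]
    xq = x[:, qtl]
    # dominance coding (-2p^2, 2pq, -2q^2) for dosages (0,1,2)
    wd = np.where(
        xq == 0, -2.0 * pq**2, np.where(xq == 1, 2.0 * pq * qq, -2.0 * qq**2)
    )
    # non-integer (imputed) dosages fall back to quadratic interpolation
    frac = (xq % 1) != 0
    if frac.any():
        P = np.broadcast_to(pq, xq.shape)
        wd = np.where(frac, -2 * P**2 + xq * 2 * P - xq**2 / 2, wd)

    traits = config.traits
    n_traits = len(traits)
    rho = config.trait_effect_corr
    if rho is None:
        eff = rng.standard_normal((config.n_qtl_additive, n_traits))
    else:
        R = np.full((n_traits, n_traits), float(rho))
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        eff = rng.standard_normal((config.n_qtl_additive, n_traits)) @ L.T
    klo, khi = config.dominance_degree_range
    degree = rng.uniform(klo, khi, size=(config.n_qtl_additive, n_traits))
    degree[~dom_qtl_mask, :] = 0.0

    base = ped.records.set_index("animal").loc[ped.animals]
    sex = (base["sex"] == "male").to_numpy(float)
    btype = base["birth_type"].to_numpy(float)
    parity = base["parity"].to_numpy(float)

    out = base.reset_index()[
        ["animal", "sire", "dam", "birth_year", "sex", "group", "birth_type",
         "parity", "genotyped", "role"]
    ].copy()

    vc: dict[str, dict[str, float]] = {}
    add_eff: dict[str, np.ndarray] = {}
    dom_eff: dict[str, np.ndarray] = {}
    tbv = {}
    ddev = {}

    for t_i, spec in enumerate(traits):
        sd = spec.sd if spec.kind != "binary" else 1.0
        var_p = sd**2
        sig_g = spec.h2 * var_p
        sig_d = spec.d2 * var_p
        sig_e = var_p - sig_g - sig_d

        a_raw = eff[:, t_i]
        d_raw = degree[:, t_i] * a_raw
        bv_raw = xa @ a_raw
        dd_raw = wd @ d_raw
        bv, fa = _scaled(bv_raw, sig_g)
        dd, fd = _scaled(dd_raw, sig_d)
        resid = rng.standard_normal(n) * np.sqrt(max(sig_e, 0.0))

        core = bv + dd + resid
        fx = np.zeros(n)
        if spec.kind != "binary" and config.fixed_effect_scale > 0:
            amp = config.fixed_effect_scale * sd
            fx = (
                amp * (sex - sex.mean())
                + 0.6 * amp * (btype - btype.mean())
                + 0.3 * amp * (parity - parity.mean())
            )

        if spec.kind == "gaussian":
            y = spec.mean + fx + core
        elif spec.kind == "count":
            y = np.rint(spec.mean + fx + core)
            y = np.clip(y, 0, None)
        else:  # binary: liability thresholded at theoretical quantile
            thr = stats.norm.ppf(1.0 - spec.prevalence) * np.sqrt(var_p)
            y = (core > thr).astype(float)

        out[spec.name] = y
        vc[spec.name] = {
            "sigma_g2": float(np.var(bv)),
            "sigma_d2": float(np.var(dd)),
            "sigma_e2": float(sig_e),
        }
        add_eff[spec.name] = a_raw * fa
        dom_eff[spec.name] = d_raw * fd
        tbv[spec.name] = bv
        ddev[spec.name] = dd

    params = TrueParams(
        seed=config.seed,
        variance_components=vc,
        qtl_index=qtl,
        qtl_additive_effects=add_eff,
        qtl_dominance_effects=dom_eff,
        breeding_values=pd.DataFrame(tbv, index=ped.animals),
        dominance_deviations=pd.DataFrame(ddev, index=ped.animals),
    )
    return out, params
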