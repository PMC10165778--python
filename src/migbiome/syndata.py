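"""Synthetic cohort generator.

Emulates a multi-ethnic, two-generation gut-microbiome cohort: an ASV count
table with planted correlated blocks of ASVs (trophic-network-like guilds),
generation-dependent abundance shifts per block, covariates (age, sex, BMI,
triglycerides) coupled to block intensities, variable library sizes, a rooted
phylogeny over the ASVs, and a taxonomy map carrying anchor-genus tags.

Generative mechanism (log-normal latent factors + multinomial):

1. each planted block b gets, per sample, a scalar latent factor
   ``z_b ~ N(0, 1)``; an ASV i in block b has log-abundance
   ``mu_i(stratum) + sigma * (sqrt(rho_b) z_b + sqrt(1 - rho_b) eps_i)``
   so any two block members correlate at rho_b on the log scale;
2. ``mu_i`` is the block's per-ethnicity baseline plus the generation shift
   (for 2nd-generation samples) plus a fixed per-ASV offset;
3. background ASVs are i.i.d. log-normal around a power-law mean profile
   (rank r gets mean ``offset - decay * ln r``) so "top-N most abundant"
   selection is non-degenerate;
4. log-abundances are softmaxed to proportions and counts drawn from a
   multinomial at a library size uniform over ``library_size_range``.

Covariates are linear in the (standardized) block factor plus Gaussian noise,
so the requested latent correlation is planted exactly; rank correlations
measured on realized counts attenuate slightly (multinomial noise, softmax).
An optional ``diversity_coupling`` tilts the per-sample background power-law
exponent with a latent correlated to a block factor, planting a rank
association between that block's abundance and alpha-diversity.
"""
from __future__ import annotations

import io as _io
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .exceptions import InvalidDesignError

__all__ = [
    "PlantedBlock",
    "CohortDesign",
    "PlantedTruth",
    "generate_tree",
    "generate_cohort",
    "default_design",
    "BLOCK_NAMES",
]

#: canonical planted-block names, matching the anchor-tag closed set
BLOCK_NAMES = ("BBB", "P_copri", "P_stercorea", "CMO")

# anchor genera per named cluster; first entries of each block get these
_ANCHOR_GENERA = {
    "BBB": [("Bacteroides", ""), ("Blautia", ""), ("Bifidobacterium", ""), ("Phocaeicola", "")],
    "P_copri": [("Prevotella", "copri")],
    "P_stercorea": [("Prevotella", "stercorea")],
    "CMO": [("Christensenella", "minuta"), ("Methanobrevibacter", "smithii"), ("Oscillibacter", "")],
}
_FILLER_GENERA = {
    "BBB": [("Parabacteroides", ""), ("Collinsella", "")],
    "P_copri": [("Alloprevotella", ""), ("Paraprevotella", "")],
    "P_stercorea": [("Prevotellamassilia", ""), ("Hallella", "")],
    "CMO": [("Ruminococcaceae", ""), ("Mogibacterium", "")],
}
_BACKGROUND_GENERA = [
    "Faecalibacterium", "Roseburia", "Agathobacter", "Ruminococcus", "Dorea",
    "Coprococcus", "Alistipes", "Akkermansia", "Dialister", "Sutterella",
    "Subdoligranulum", "Gemmiger", "Anaerostipes", "Fusicatenibacter",
    "Lachnospira", "Eubacterium", "Streptococcus", "Veillonella",
]


@dataclass
class PlantedBlock:
    """One planted correlated ASV block (a trophic-network stand-in)."""

    name: str
    asv_ids: list[str]
    baseline_logabundance: dict[str, float]
    generation_shift: dict[str, float]
    within_block_correlation: float = 0.7

    def validate(self) -> None:
        if not self.asv_ids:
            raise InvalidDesignError(f"block {self.name!r} has no ASVs")
        if not (0 < self.within_block_correlation < 1):
            raise InvalidDesignError(
                f"block {self.name!r}: within_block_correlation must lie in (0, 1)"
            )
        for eth, s in self.generation_shift.items():
            if abs(s) > 3:
                raise InvalidDesignError(
                    f"block {self.name!r}: |generation_shift| for {eth} exceeds 3 log units"
                )


@dataclass
class CohortDesign:
    """Full specification of a synthetic cohort."""

    ethnicities: list[str]
    n_per_generation: dict[str, tuple[int, int]]
    n_asvs: int
    blocks: list[PlantedBlock]
    library_size_range: tuple[int, int] = (16000, 45000)
    covariate_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    diversity_coupling: tuple[str, float] | None = None
    seed: int = 0
    background_decay: float = 1.0
    diversity_gain: float = 0.45
    asv_log_sd: float = 1.0
    sibling_pair_fraction: float = 0.1

    def validate(self) -> None:
        if not self.ethnicities:
            raise InvalidDesignError("at least one ethnicity required")
        for eth in self.ethnicities:
            if eth not in self.n_per_generation:
                raise InvalidDesignError(f"missing sample sizes for {eth!r}")
            n1, n2 = self.n_per_generation[eth]
            if n1 < 2 or n2 < 2:
                raise InvalidDesignError(
                    f"{eth!r}: need >= 2 samples per generation, got ({n1}, {n2})"
                )
        seen: set[str] = set()
        block_names = set()
        for b in self.blocks:
            b.validate()
            block_names.add(b.name)
            overlap = seen.intersection(b.asv_ids)
            if overlap:
                raise InvalidDesignError(f"block ASV sets overlap: {sorted(overlap)[:5]}")
            seen.update(b.asv_ids)
        if len(seen) > self.n_asvs:
            raise InvalidDesignError("blocks reference more ASVs than n_asvs")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise InvalidDesignError("library_size_range must satisfy 1 <= min <= max")
        for cov, (bname, r) in self.covariate_effects.items():
            if bname not in block_names:
                raise InvalidDesignError(f"covariate {cov!r} targets unknown block {bname!r}")
            if not (-1 <= r <= 1):
                raise InvalidDesignError(f"covariate {cov!r}: correlation must lie in [-1, 1]")
        if self.diversity_coupling is not None:
            bname, r = self.diversity_coupling
            if bname not in block_names:
                raise InvalidDesignError(f"diversity_coupling targets unknown block {bname!r}")
            if not (-1 <= r <= 1):
                raise InvalidDesignError("diversity_coupling correlation must lie in [-1, 1]")


@dataclass
class PlantedTruth:
    """Ground truth written alongside a generated cohort for recovery tests."""

    membership: dict[str, str]              # ASV id -> block name or "background"
    block_intensity: pd.DataFrame           # samples x blocks, latent factors z_b
    covariate_params: dict
    true_block_share: pd.DataFrame | None = None  # samples x blocks, softmax shares

    def to_json(self) -> str:
        d = {
            "membership": self.membership,
            "block_intensity": self.block_intensity.to_dict(orient="index"),
            "covariate_params": self.covariate_params,
        }
        if self.true_block_share is not None:
            d["true_block_share"] = self.true_block_share.to_dict(orient="index")
        return json.dumps(d, indent=1, sort_keys=True)


def _asv_ids(n: int) -> list[str]:
    return [f"ASV{i + 1:04d}" for i in range(n)]


def generate_tree(
    n_asvs: int,
    block_membership: dict[str, str] | None = None,
    seed: int = 0,
    n_sibling_pairs: int | None = None,
    sibling_pair_fraction: float = 0.0,
    pair_height: float = 0.05,
    asv_ids: list[str] | None = None,
) -> skbio.TreeNode:
    """Random rooted ultrametric binary tree over ASV tips.

    A configurable number of tip pairs are planted as cherries at node height
    ``pair_height`` (<= 0.10, hence agglomerable at the genus-like threshold);
    every other internal node sits at height > 0.10. Block members, when a
    membership map is given, coalesce within their block before blocks join,
    so planted guilds are phylogenetically coherent clades.
    """
    if n_asvs < 2:
        raise InvalidDesignError("generate_tree requires n_asvs >= 2")
    if pair_height <= 0 or pair_height > 0.10:
        raise InvalidDesignError("pair_height must lie in (0, 0.10]")
    rng = np.random.default_rng(seed)
    ids = list(asv_ids) if asv_ids is not None else _asv_ids(n_asvs)
    if len(ids) != n_asvs:
        raise InvalidDesignError("asv_ids length must equal n_asvs")

    if n_sibling_pairs is None:
        n_sibling_pairs = int(round(sibling_pair_fraction * n_asvs / 2))
    if n_sibling_pairs > n_asvs // 2:
        raise InvalidDesignError("too many sibling pairs for the tip count")

    membership = block_membership or {}
    groups: dict[str, list[str]] = {}
    for a in ids:
        groups.setdefault(membership.get(a, "background"), []).append(a)

    # each subtree: (newick fragment without trailing length, height)
    forest: dict[str, list[tuple[str, float]]] = {}
    pairs_left = n_sibling_pairs
    for gname in sorted(groups):
        members = groups[gname]
        sub: list[tuple[str, float]] = []
        i = 0
        # plant cherries greedily from the front of each group
        while pairs_left > 0 and i + 1 < len(members):
            a, b = members[i], members[i + 1]
            sub.append((f"({a}:{pair_height:.6f},{b}:{pair_height:.6f})", pair_height))
            i += 2
            pairs_left -= 1
        for a in members[i:]:
            sub.append((a, 0.0))
        forest[gname] = sub

    def _join_all(sub: list[tuple[str, float]]) -> tuple[str, float]:
        while len(sub) > 1:
            i, j = sorted(rng.choice(len(sub), size=2, replace=False))
            (na, ha), (nb, hb) = sub[j], sub[i]
            h = max(0.30, ha, hb) + rng.uniform(0.02, 0.12)
            frag = f"({na}:{h - ha:.6f},{nb}:{h - hb:.6f})"
            sub = [s for k, s in enumerate(sub) if k not in (i, j)] + [(frag, h)]
        return sub[0]

    roots = [_join_all(forest[g]) for g in sorted(forest)]
    newick, _ = _join_all(roots)
    tree = skbio.TreeNode.read(_io.StringIO(newick + ";"))
    tree.length = None
    return tree


def _spearman_to_pearson(r: float) -> float:
    """Pearson correlation of a bivariate normal whose Spearman rho is r."""
    return float(np.clip(2.0 * np.sin(np.pi * r / 6.0), -1.0, 1.0))


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    return float(m + np.log(np.exp(v - m).sum()))


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent deterministic stream keyed by a string label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def generate_cohort(design: CohortDesign):
    """Generate (counts, metadata, tree, taxonomy, truth) for a design.

    Counts are a samples x ASVs integer DataFrame; each row sums exactly to
    its drawn library size. Deterministic given ``design.seed``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    ids = _asv_ids(design.n_asvs)
    id_set = set(ids)
    for b in design.blocks:
        missing = [a for a in b.asv_ids if a not in id_set]
        if missing:
            raise InvalidDesignError(
                f"block {b.name!r} references ids outside ASV{1:04d}..ASV{design.n_asvs:04d}: "
                f"{missing[:5]}"
            )

    membership = {a: "background" for a in ids}
    for b in design.blocks:
        for a in b.asv_ids:
            membership[a] = b.name

    background = [a for a in ids if membership[a] == "background"]
    # fixed per-ASV structure, independent of sample draws
    struct_rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xA5]))
    bg_rank = {a: r + 1 for r, a in enumerate(background)}
    block_offsets = {
        a: struct_rng.normal(0.0, 0.5)
        for b in design.blocks
        for a in b.asv_ids
    }

    sigma = design.asv_log_sd
    rows = []
    meta_rows = []
    z_rows = []
    share_rows = []
    sample_ids = []
    lib_lo, lib_hi = design.library_size_range
    div_block, div_r = design.diversity_coupling or (None, 0.0)

    # fixed per-ASV lookup arrays so each sample is one vectorized draw
    bg_mask = np.array([membership[a] == "background" for a in ids])
    log_rank = np.array([np.log(bg_rank[a]) if bg_mask[i] else 0.0 for i, a in enumerate(ids)])
    blk_index = np.full(design.n_asvs, -1)
    offsets = np.zeros(design.n_asvs)
    sqrt_rho = np.zeros(design.n_asvs)
    sqrt_1m_rho = np.ones(design.n_asvs)
    for bi, b in enumerate(design.blocks):
        for a in b.asv_ids:
            i = ids.index(a)
            blk_index[i] = bi
            offsets[i] = block_offsets[a]
            sqrt_rho[i] = np.sqrt(b.within_block_correlation)
            sqrt_1m_rho[i] = np.sqrt(1 - b.within_block_correlation)

    # reference log total mass of the untilted background profile
    log_mass0 = _logsumexp(-design.background_decay * log_rank[bg_mask])

    for eth in design.ethnicities:
        base_vec = np.zeros(design.n_asvs)
        shift_vec = np.zeros(design.n_asvs)
        for bi, b in enumerate(design.blocks):
            sel = blk_index == bi
            base_vec[sel] = b.baseline_logabundance.get(eth, 0.0)
            shift_vec[sel] = b.generation_shift.get(eth, 0.0)
        n1, n2 = design.n_per_generation[eth]
        for gen, n in ((1, n1), (2, n2)):
            srng = _substream(design.seed, f"{eth}|gen{gen}")
            mu_vec = base_vec + (gen == 2) * shift_vec + offsets
            for k in range(n):
                sid = f"{eth}.g{gen}.{k + 1:03d}"
                sample_ids.append(sid)
                z_vals = srng.normal(size=len(design.blocks))
                z = {b.name: float(z_vals[bi]) for bi, b in enumerate(design.blocks)}
                eps_div = srng.normal()
                # background: per-sample power-law tilt plants the
                # diversity coupling (flatter profile -> higher Shannon)
                if div_block is not None:
                    # requested rank correlation -> Pearson on the latent
                    # scale, divided by the mechanism's measured ceiling
                    # (realized rho at a perfectly coupled tilt is ~0.92:
                    # multinomial noise and the block share itself also move
                    # Shannon) so that the planted value is what is realized.
                    # The coupled latent includes the block's generation
                    # shift (in factor units) so diversity tracks the block
                    # across generations, as observed in migrant cohorts.
                    rr = np.clip(_spearman_to_pearson(div_r) / 0.92, -1.0, 1.0)
                    dblk = next(b for b in design.blocks if b.name == div_block)
                    z_eff = z[div_block] + (gen == 2) * dblk.generation_shift.get(eth, 0.0) / (
                        sigma * np.sqrt(dblk.within_block_correlation)
                    )
                    u = rr * z_eff + np.sqrt(1 - rr**2) * eps_div
                else:
                    u = 0.0
                decay = design.background_decay * np.exp(-design.diversity_gain * u)
                eps = srng.normal(size=design.n_asvs)
                z_per_asv = np.where(blk_index >= 0, z_vals[blk_index], 0.0)
                # tilting the power-law exponent changes background evenness
                # (hence Shannon) while the normalization keeps the total
                # background mass fixed, preserving block shares
                bg_prof = -decay * log_rank[bg_mask]
                bg_prof += log_mass0 - _logsumexp(bg_prof)
                loga = np.empty(design.n_asvs)
                loga[bg_mask] = bg_prof + sigma * eps[bg_mask]
                loga[~bg_mask] = (
                    mu_vec[~bg_mask]
                    + sigma
                    * (sqrt_rho * z_per_asv + sqrt_1m_rho * eps)[~bg_mask]
                )
                p = np.exp(loga - loga.max())
                p /= p.sum()
                lib = int(srng.integers(lib_lo, lib_hi + 1))
                rows.append(srng.multinomial(lib, p))
                share_rows.append(
                    {b.name: float(p[blk_index == bi].sum())
                     for bi, b in enumerate(design.blocks)}
                )

                covs = _draw_covariates(design, z, gen, srng)
                meta_rows.append(
                    {"sample_id": sid, "ethnicity": eth, "generation": gen, **covs}
                )
                z_rows.append(z)

    table = pd.DataFrame(np.vstack(rows), index=sample_ids, columns=ids)
    table.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    # covariate coupling: the covariate is linear in the normal-scores of the
    # realized block relative abundance plus Gaussian noise, so the requested
    # rank correlation is planted with minimal attenuation
    if design.covariate_effects:
        from scipy.stats import rankdata, norm

        rel_tot = table.sum(axis=1).to_numpy(dtype=float)
        for cov, (bname, r) in sorted(design.covariate_effects.items()):
            blk = next(b for b in design.blocks if b.name == bname)
            share = table[blk.asv_ids].sum(axis=1).to_numpy() / rel_tot
            scores = norm.ppf((rankdata(share) - 0.5) / len(share))
            crng = _substream(design.seed, f"cov|{cov}")
            rr = _spearman_to_pearson(r)
            latent = rr * scores + np.sqrt(1 - rr**2) * crng.normal(size=len(share))
            if cov == "age":
                meta["age"] = np.round(42.0 + 12.0 * latent, 1)
            elif cov == "bmi":
                meta["bmi"] = np.round(26.0 + 4.0 * latent, 2)
            elif cov == "triglycerides":
                meta["triglycerides"] = np.round(np.exp(0.2 + 0.5 * latent), 3)
            else:
                meta[cov] = np.round(latent, 4)
    truth = PlantedTruth(
        membership=membership,
        block_intensity=pd.DataFrame(z_rows, index=sample_ids),
        true_block_share=pd.DataFrame(share_rows, index=sample_ids),
        covariate_params={
            "covariate_effects": {c: list(v) for c, v in design.covariate_effects.items()},
            "diversity_coupling": list(design.diversity_coupling)
            if design.diversity_coupling
            else None,
        },
    )
    tree = generate_tree(
        design.n_asvs,
        block_membership=membership,
        seed=design.seed + 1,
        sibling_pair_fraction=design.sibling_pair_fraction,
        asv_ids=ids,
    )
    taxonomy = _make_taxonomy(design, membership, struct_rng)
    return table, meta, tree, taxonomy, truth


def _draw_covariates(design, z, gen, srng) -> dict:
    """Age, sex, BMI, triglycerides; coupled to block factors where requested."""

    def coupled(cov: str, default: float):
        if cov in design.covariate_effects:
            bname, r = design.covariate_effects[cov]
            return r * z[bname] + np.sqrt(1 - r**2) * srng.normal()
        return default

    # absent a planted effect, age confounds with generation (migrant cohorts:
    # 1st generation older), BMI/triglycerides are plain noise
    age_lat = coupled("age", None)
    if age_lat is None:
        age = srng.normal(52.0 if gen == 1 else 34.0, 8.0)
    else:
        age = 42.0 + 12.0 * age_lat
    bmi = 26.0 + 4.0 * coupled("bmi", srng.normal())
    trig = float(np.exp(0.2 + 0.5 * coupled("triglycerides", srng.normal())))
    sex = "F" if srng.random() < 0.5 else "M"
    return {
        "age": round(float(age), 1),
        "sex": sex,
        "bmi": round(float(bmi), 2),
        "triglycerides": round(trig, 3),
    }


def _make_taxonomy(design, membership, rng) -> pd.DataFrame:
    recs = []
    block_by_name = {b.name: b for b in design.blocks}
    for a in sorted(membership):
        bn = membership[a]
        if bn == "background":
            g = _BACKGROUND_GENERA[zlib.crc32(a.encode()) % len(_BACKGROUND_GENERA)]
            recs.append({"asv_id": a, "genus": g, "species": "", "anchor": "none"})
        else:
            blk = block_by_name[bn]
            pos = blk.asv_ids.index(a)
            anchors = _ANCHOR_GENERA.get(bn, [("Unknown", "")])
            fillers = _FILLER_GENERA.get(bn, [("Unknown", "")])
            n_anchor = max(3, int(0.6 * len(blk.asv_ids)))
            n_anchor = min(n_anchor, len(blk.asv_ids))
            if pos < n_anchor:
                g, sp = anchors[pos % len(anchors)]
                tag = bn
            else:
                g, sp = fillers[pos % len(fillers)]
                tag = "none"
            recs.append({"asv_id": a, "genus": g, "species": sp, "anchor": tag})
    tax = pd.DataFrame(recs).set_index("asv_id")
    return tax


def default_design(
    seed: int = 0,
    n_per_generation: dict[str, tuple[int, int]] | None = None,
    n_asvs: int = 600,
) -> CohortDesign:
    """The default five-ethnicity, two-generation cohort design.

    Mirrors the study design this generator stands in for: five ethnic strata
    with 60-150 samples per generation, 600 ASVs, four planted blocks (BBB,
    P. copri network, P. stercorea network, CMO), Prevotella-type blocks more
    abundant in the Turkish/Moroccan/South-Asian strata and shifted downward
    in the 2nd generation of the Turkish/Moroccan/Dutch strata while BBB
    shifts upward there; BMI and triglycerides negatively coupled to the CMO
    block and alpha-diversity positively coupled to it.
    """
    eths = ["Dutch", "Moroccan", "Turkish", "AfricanSurinamese", "SouthAsianSurinamese"]
    if n_per_generation is None:
        n_per_generation = {
            "Dutch": (150, 120),
            "Moroccan": (120, 90),
            "Turkish": (110, 80),
            "AfricanSurinamese": (90, 70),
            "SouthAsianSurinamese": (80, 60),
        }
    ids = _asv_ids(n_asvs)
    sizes = {"BBB": 40, "P_copri": 30, "P_stercorea": 25, "CMO": 25}
    blocks = []
    start = 0
    shifted = ("Dutch", "Moroccan", "Turkish")
    base = {
        "BBB": {
            "Dutch": -2.3, "Moroccan": -2.9, "Turkish": -2.9,
            "AfricanSurinamese": -2.6, "SouthAsianSurinamese": -2.9,
        },
        "P_copri": {
            "Dutch": -3.3, "Moroccan": -2.4, "Turkish": -2.4,
            "AfricanSurinamese": -3.0, "SouthAsianSurinamese": -2.5,
        },
        "P_stercorea": {
            "Dutch": -3.6, "Moroccan": -2.8, "Turkish": -2.8,
            "AfricanSurinamese": -3.2, "SouthAsianSurinamese": -2.8,
        },
        "CMO": {
            "Dutch": -3.0, "Moroccan": -3.0, "Turkish": -3.0,
            "AfricanSurinamese": -3.0, "SouthAsianSurinamese": -3.0,
        },
    }
    shift = {
        "BBB": {e: (+0.5 if e in shifted else 0.0) for e in eths},
        "P_copri": {e: (-0.8 if e in shifted else 0.0) for e in eths},
        "P_stercorea": {e: (-0.8 if e in shifted else 0.0) for e in eths},
        "CMO": {e: (-0.5 if e in shifted else 0.0) for e in eths},
    }
    for name in BLOCK_NAMES:
        n = sizes[name]
        blocks.append(
            PlantedBlock(
                name=name,
                asv_ids=ids[start : start + n],
                baseline_logabundance=base[name],
                generation_shift=shift[name],
                within_block_correlation=0.7,
            )
        )
        start += n
    return CohortDesign(
        ethnicities=eths,
        n_per_generation=n_per_generation,
        n_asvs=n_asvs,
        blocks=blocks,
        library_size_range=(16000, 45000),
        covariate_effects={"bmi": ("CMO", -0.2), "triglycerides": ("CMO", -0.12)},
        # the diversity coupling tilts the whole background profile and so
        # induces diffuse background-block correlations that contaminate
        # heatmap blocks; it is reserved for dedicated association designs
        diversity_coupling=None,
        seed=seed,
    )
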