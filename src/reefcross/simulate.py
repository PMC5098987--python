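"""Synthetic breeding designs, life-history outcomes and symbiont count tables.

The generator emulates a two-population factorial coral cross: dams and sires
from two source reefs (coded ``O`` and ``W``), ~25 families with three culture
replicates each, overdispersed settlement counts driven by dam/sire/interaction
random effects on the log scale, juvenile survival driven by settlement plus a
dam effect, and negative-binomial OTU counts whose composition differs between
high- and low-mortality families.  Multi-copy variant pairs (fixed abundance
ratio, high sequence identity) and an opportunistic type enriched in the
high-mortality class are planted so downstream stages can be tested against
known truth.

Every function is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountTable

__all__ = [
    "CrossDesign",
    "EffectParams",
    "CommunityParams",
    "generate_cross_design",
    "simulate_life_history",
    "assign_mortality_class",
    "make_sequencing_metadata",
    "simulate_symbiont_table",
    "simulate_study",
]

LN2 = float(np.log(2.0))


@dataclass
class CrossDesign:
    """Dams, sires and the family (dam x sire) lattice with lineage labels."""

    dams: list[tuple[str, str]]  # (id, population)
    sires: list[tuple[str, str]]
    families: list[tuple[str, str, str]]  # (family_id, dam_id, sire_id)
    replicates_per_family: int = 3

    def __post_init__(self) -> None:
        fids = [f for f, _, _ in self.families]
        if len(set(fids)) != len(fids):
            raise ValueError("family ids not unique")
        for _, d, s in self.families:
            if d == s:
                raise ValueError(f"self-cross {d} x {s} not permitted")

    @property
    def dam_pop(self) -> dict[str, str]:
        return dict(self.dams)

    @property
    def sire_pop(self) -> dict[str, str]:
        return dict(self.sires)

    @property
    def lineage(self) -> dict[str, str]:
        dp, sp = self.dam_pop, self.sire_pop
        return {
            f: ("purebred" if dp[d] == sp[s] else "hybrid")
            for f, d, s in self.families
        }

    def to_frame(self) -> pd.DataFrame:
        dp, sp = self.dam_pop, self.sire_pop
        rows = [
            {
                "family_id": f,
                "dam_id": d,
                "sire_id": s,
                "dam_population": dp[d],
                "sire_population": sp[s],
                "lineage": "purebred" if dp[d] == sp[s] else "hybrid",
            }
            for f, d, s in self.families
        ]
        return pd.DataFrame(rows)


def _default_weight_means(dam_ids: list[str], dam_pop: dict[str, str]) -> dict[str, float]:
    # Orpheus dams produce heavier larvae than Wilkie dams; the defaults span
    # the observed extremes of roughly 17.6 down to 9.7 ug dry weight.
    out: dict[str, float] = {}
    o = [d for d in dam_ids if dam_pop[d] == "O"]
    w = [d for d in dam_ids if dam_pop[d] == "W"]
    for i, d in enumerate(sorted(o)):
        out[d] = 14.5 + 3.1 * (i / max(len(o) - 1, 1))
    for i, d in enumerate(sorted(w)):
        out[d] = 9.7 + 2.5 * (i / max(len(w) - 1, 1))
    return out


@dataclass
class EffectParams:
    """Latent-scale parameters of the life-history generator.

    Settlement counts per culture replicate are Poisson with a log-scale
    linear predictor ``beta0 + u_dam + v_sire + w_damxsire + eps_obs`` where
    the four effects are independent Normals with the given variances (the
    observation-level effect models overdispersion).  Juvenile survivors are
    negative binomial with mean ``exp(beta0_survival + slope * settled +
    u'_dam)``, right-truncated at the settlement count.
    """

    beta0_settlement: float = np.log(40.0)
    var_dam: float = 0.4
    var_sire: float = 0.6
    var_interaction: float = 0.1
    var_obs: float = 0.5
    beta0_survival: float = 2.0
    slope_settlement: float = 0.02
    var_dam_survival: float = 2.25
    var_family_survival: float = 2.25
    nb_dispersion: float = 5.0
    weight_mean_by_dam: dict[str, float] | None = None
    weight_sd: float = 2.0
    culture_death_prob_by_dam: dict[str, float] | None = None
    culture_death_prob_default: float = 0.03

    def __post_init__(self) -> None:
        for name in ("var_dam", "var_sire", "var_interaction", "var_obs",
                     "var_dam_survival", "var_family_survival"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def generate_cross_design(
    n_dams_per_pop: int,
    n_sires_per_pop: int,
    seed: int,
    n_families: int | None = 25,
    replicates_per_family: int = 3,
) -> CrossDesign:
    """Generate a two-population factorial cross.

    Parent colonies serve as both dam and sire (self-crosses excluded).  When
    ``n_families`` is smaller than the full lattice, that many dam x sire
    pairs are drawn without replacement, ensuring every cross class
    (OO, OW, WO, WW) is represented when the lattice permits.
    """
    if n_dams_per_pop < 1 or n_sires_per_pop < 1:
        raise ValueError("need at least one parent per population")
    rng = np.random.default_rng(seed)
    dams = [(f"O{i + 1}", "O") for i in range(n_dams_per_pop)] + [
        (f"W{i + 1}", "W") for i in range(n_dams_per_pop)
    ]
    sires = [(f"O{i + 1 + n_dams_per_pop}", "O") for i in range(n_sires_per_pop)] + [
        (f"W{i + 1 + n_dams_per_pop}", "W") for i in range(n_sires_per_pop)
    ]
    lattice = [(d, s) for d, _ in dams for s, _ in sires if d != s]
    if n_families is None or n_families >= len(lattice):
        chosen = lattice
    else:
        dp, sp = dict(dams), dict(sires)
        by_class: dict[str, list[tuple[str, str]]] = {}
        for d, s in lattice:
            by_class.setdefault(dp[d] + sp[s], []).append((d, s))
        chosen = []
        # one pair per cross class first, then fill uniformly
        for cls in sorted(by_class):
            pairs = by_class[cls]
            chosen.append(pairs[rng.integers(len(pairs))])
        remaining = [p for p in lattice if p not in chosen]
        k = n_families - len(chosen)
        if k > 0:
            idx = rng.choice(len(remaining), size=k, replace=False)
            chosen.extend(remaining[i] for i in sorted(idx))
        chosen = chosen[:n_families]
        chosen.sort(key=lattice.index)
    families = [(f"F{i + 1}", d, s) for i, (d, s) in enumerate(chosen)]
    return CrossDesign(
        dams=dams, sires=sires, families=families,
        replicates_per_family=replicates_per_family,
    )


def simulate_life_history(
    design: CrossDesign, params: EffectParams, seed: int
) -> pd.DataFrame:
    """Simulate per family x replicate life-history outcomes.

    Returns a table with columns family_id, replicate, dam_id, sire_id,
    culture_alive, larval_weight_ug, settled, survived.  Survivors never
    exceed settlers (the biology forces the truncation even though the
    fitted models do not state it).
    """
    rng = np.random.default_rng(seed)
    dam_ids = [d for d, _ in design.dams]
    sire_ids = [s for s, _ in design.sires]
    weight_means = params.weight_mean_by_dam or _default_weight_means(
        dam_ids, design.dam_pop
    )
    death_probs = params.culture_death_prob_by_dam or {}

    u_dam = dict(zip(dam_ids, rng.normal(0.0, np.sqrt(params.var_dam), len(dam_ids))))
    v_sire = dict(zip(sire_ids, rng.normal(0.0, np.sqrt(params.var_sire), len(sire_ids))))
    w_fam = {
        f: rng.normal(0.0, np.sqrt(params.var_interaction))
        for f, _, _ in design.families
    }
    u_dam_surv = dict(
        zip(dam_ids, rng.normal(0.0, np.sqrt(params.var_dam_survival), len(dam_ids)))
    )
    w_fam_surv = {
        f: rng.normal(0.0, np.sqrt(params.var_family_survival))
        for f, _, _ in design.families
    }

    rows = []
    for fam, dam, sire in design.families:
        p_dead = death_probs.get(dam, params.culture_death_prob_default)
        for rep in range(1, design.replicates_per_family + 1):
            alive = bool(rng.random() >= p_dead)
            weight = max(rng.normal(weight_means.get(dam, 12.0), params.weight_sd), 0.0)
            if alive:
                eps = rng.normal(0.0, np.sqrt(params.var_obs)) if params.var_obs > 0 else 0.0
                eta = (
                    params.beta0_settlement
                    + u_dam[dam]
                    + v_sire[sire]
                    + w_fam[fam]
                    + eps
                )
                settled = int(rng.poisson(np.exp(eta)))
            else:
                settled = 0
            if settled > 0:
                mu = np.exp(
                    min(
                        params.beta0_survival
                        + params.slope_settlement * settled
                        + u_dam_surv[dam]
                        + w_fam_surv[fam],
                        np.log(10.0 * settled),  # truncation at settled dominates
                    )
                )
                theta = params.nb_dispersion
                survived = int(rng.negative_binomial(theta, theta / (theta + mu)))
                survived = min(survived, settled)
            else:
                survived = 0
            rows.append(
                {
                    "family_id": fam,
                    "replicate": rep,
                    "dam_id": dam,
                    "sire_id": sire,
                    "culture_alive": int(alive),
                    "larval_weight_ug": round(weight, 2),
                    "settled": settled,
                    "survived": survived,
                }
            )
    return pd.DataFrame(rows)


def assign_mortality_class(
    life: pd.DataFrame, high_threshold: float = 90.0, low_threshold: float = 10.0
) -> pd.DataFrame:
    """Per-family percent juvenile mortality and its class.

    A family is ``high`` only when mortality exceeds ``high_threshold`` percent
    and ``low`` only below ``low_threshold``; everything else (including
    families with no settlers) is ``unassigned``.
    """
    per_fam = life.groupby("family_id", sort=False).agg(
        dam_id=("dam_id", "first"),
        sire_id=("sire_id", "first"),
        settled=("settled", "sum"),
        survived=("survived", "sum"),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mortality = 100.0 * (1.0 - per_fam["survived"] / per_fam["settled"])
    per_fam["percent_mortality"] = mortality
    cls = np.full(len(per_fam), "unassigned", dtype=object)
    ok = per_fam["settled"] > 0
    cls[(mortality > high_threshold) & ok] = "high"
    cls[(mortality < low_threshold) & ok] = "low"
    per_fam["mortality_class"] = cls
    return per_fam.reset_index()


def make_sequencing_metadata(
    design: CrossDesign,
    family_classes: pd.DataFrame,
    seed: int,
    n_high_families: int = 5,
    n_low_families: int = 3,
    juveniles_range: tuple[int, int] = (1, 13),
) -> pd.DataFrame:
    """Build a juvenile sample-metadata table for the sequencing subset.

    Mirrors the study design: the highest- and lowest-mortality families are
    sequenced (a handful of each), with 1-13 juveniles per family.
    ``family_classes`` is the output of :func:`assign_mortality_class`.
    """
    rng = np.random.default_rng(seed)
    dp, sp = design.dam_pop, design.sire_pop
    fam_info = {f: (d, s) for f, d, s in design.families}
    high = family_classes[family_classes["mortality_class"] == "high"]
    low = family_classes[family_classes["mortality_class"] == "low"]
    high = high.sort_values("percent_mortality", ascending=False).head(n_high_families)
    low = low.sort_values("percent_mortality").head(n_low_families)
    rows = []
    for _, fam_row in pd.concat([high, low]).iterrows():
        fam = fam_row["family_id"]
        dam, sire = fam_info[fam]
        n_juv = int(rng.integers(juveniles_range[0], juveniles_range[1] + 1))
        for j in range(1, n_juv + 1):
            rows.append(
                {
                    "sample_id": f"{fam}_J{j}",
                    "family_id": fam,
                    "dam_id": dam,
                    "sire_id": sire,
                    "dam_population": dp[dam],
                    "sire_population": sp[sire],
                    "mortality_class": fam_row["mortality_class"],
                }
            )
    return pd.DataFrame(rows, columns=[
        "sample_id", "family_id", "dam_id", "sire_id",
        "dam_population", "sire_population", "mortality_class",
    ])


# ---------------------------------------------------------------------------
# symbiont community generator
# ---------------------------------------------------------------------------

@dataclass
class CommunityParams:
    """Parameters of the symbiont count-table generator.

    Per-sample expected composition is ``softmax(baseline + class_shift * ln2
    * is_high + noise)`` scaled by a library size drawn uniformly from
    ``library_size_range`` (the study's mapped-read range); counts are
    negative binomial around those means.  ``class_log2_shift`` entries are
    per-OTU log2 fold differences of the high-mortality class relative to
    low.  ``variant_pairs`` plant multi-copy pairs (b tracks a at a fixed
    abundance ratio, sequences near a target percent identity);
    ``opportunist_otu`` marks the planted environmental opportunist.
    ``n_exclusive_high`` leading otherwise-rare OTUs are present only in the
    high-mortality class, giving that class the higher richness.
    """

    n_otus: int = 60
    baseline_log_abundance: np.ndarray | None = None
    class_log2_shift: np.ndarray | None = None
    library_size_range: tuple[int, int] = (20_000, 180_000)
    nb_dispersion_otu: float = 3.0
    sample_noise_sd: float = 0.6
    variant_pairs: list[tuple[str, str, float, float]] = field(
        default_factory=lambda: [
            ("OTU5", "OTU51", 3.0, 98.0),
            ("OTU7", "OTU52", 2.0, 96.0),
        ]
    )
    variant_pair_cv: float = 0.05
    opportunist_otu: str = "OTU9"
    opportunist_log2_shift: float = 2.8
    n_exclusive_high: int = 8
    seq_length: int = 300

    def __post_init__(self) -> None:
        lo, hi = self.library_size_range
        if not (0 < lo < hi):
            raise ValueError("degenerate library_size_range")
        for a, b, ratio, sim in self.variant_pairs:
            if ratio <= 0:
                raise ValueError("variant-pair ratio must be positive")
            if not (0.0 <= sim <= 100.0):
                raise ValueError("similarity target must be in [0, 100]")

    def otu_ids(self) -> list[str]:
        return [f"OTU{i + 1}" for i in range(self.n_otus)]


def _default_community(params: CommunityParams, rng: np.random.Generator):
    """Baseline log abundances and class shifts mirroring the study structure."""
    n = params.n_otus
    ids = params.otu_ids()
    if params.baseline_log_abundance is not None:
        base = np.asarray(params.baseline_log_abundance, dtype=float).copy()
    else:
        # a few dominant types plus a long tail of rare OTUs
        base = -1.2 * np.arange(n) / 6.0
        base += rng.normal(0.0, 0.3, n)
        base[0] = 2.0  # dominant beneficial type (A3-like)
    if params.class_log2_shift is not None:
        shift = np.asarray(params.class_log2_shift, dtype=float).copy()
    else:
        shift = np.zeros(n)
        # beneficial types depleted in the high-mortality class ...
        for i, s in zip((0, 1, 2, 3, 4), (-1.8, -1.5, -2.0, -1.6, -1.4)):
            shift[i] = s
        # ... and the opportunist enriched about sevenfold
        shift[ids.index(params.opportunist_otu)] = params.opportunist_log2_shift
    return base, shift


def _exclusive_high_ids(params: CommunityParams) -> list[str]:
    """Rare OTUs present only in high-mortality samples (richness surplus)."""
    reserved = {params.opportunist_otu}
    for a, b, _, _ in params.variant_pairs:
        reserved |= {a, b}
    ids = [i for i in params.otu_ids()[10:] if i not in reserved]
    return ids[: params.n_exclusive_high]


def _mutate_to_identity(
    ancestor: str, target: float, rng: np.random.Generator
) -> str:
    """Derive a variant sequence near a target aligned percent identity.

    Point substitutions set the divergence; below 97% identity a short
    deletion block (1-3 bp) is also introduced so that alignment-free
    distances fall below the aligned identity, as real intragenomic variants
    with deletion blocks do.
    """
    bases = "ACGT"
    seq = list(ancestor)
    n = len(seq)
    n_del = 0
    if target < 97.0:
        n_del = int(rng.integers(1, 4))
    n_sub = max(int(round(n * (1.0 - target / 100.0))) - n_del, 0)
    pos = rng.choice(n, size=min(n_sub + n_del, n), replace=False)
    sub_pos, del_pos = pos[:n_sub], sorted(pos[n_sub:], reverse=True)
    for p in sub_pos:
        alt = [b for b in bases if b != seq[p]]
        seq[p] = alt[rng.integers(3)]
    for p in del_pos:
        del seq[p]
    return "".join(seq)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def simulate_symbiont_table(
    metadata: pd.DataFrame, params: CommunityParams, seed: int
) -> tuple[CountTable, dict[str, str], dict]:
    """Simulate an OTU count table plus representative sequences.

    Requires metadata with high/low mortality classes assigned.  Returns the
    count table, the ``{otu_id: sequence}`` map and a truth dict recording
    every planted parameter (shifts, pairs, exclusive OTUs).
    """
    classes = set(metadata["mortality_class"])
    if not {"high", "low"} <= classes:
        raise ValueError("metadata must contain both high and low mortality classes")
    rng = np.random.default_rng(seed)
    ids = params.otu_ids()
    index = {o: i for i, o in enumerate(ids)}
    base, shift = _default_community(params, rng)
    exclusive = _exclusive_high_ids(params)
    samples = list(metadata["sample_id"])
    is_high = (metadata["mortality_class"] == "high").to_numpy()

    lo, hi = params.library_size_range
    lib = rng.integers(lo, hi + 1, size=len(samples))
    counts = np.zeros((params.n_otus, len(samples)), dtype=np.int64)
    theta = params.nb_dispersion_otu
    for j in range(len(samples)):
        loglam = base + shift * LN2 * float(is_high[j])
        loglam = loglam + rng.normal(0.0, params.sample_noise_sd, params.n_otus)
        for o in exclusive:
            if not is_high[j]:
                loglam[index[o]] = -np.inf
        p_comp = np.exp(loglam - np.max(loglam[np.isfinite(loglam)]))
        p_comp[~np.isfinite(p_comp)] = 0.0
        p_comp /= p_comp.sum()
        mu = lib[j] * p_comp
        pos = mu > 0
        counts[pos, j] = rng.negative_binomial(theta, theta / (theta + mu[pos]))

    # planted multi-copy pairs: b tracks a at a fixed ratio with small noise
    pair_theta = 1.0 / params.variant_pair_cv**2
    for a, b, ratio, _sim in params.variant_pairs:
        ca = counts[index[a]]
        mu_b = ratio * ca.astype(float)
        cb = np.zeros_like(ca)
        pos = mu_b > 0
        cb[pos] = rng.negative_binomial(
            pair_theta, pair_theta / (pair_theta + mu_b[pos])
        )
        counts[index[b]] = cb

    # sequences: unrelated OTUs are independent random sequences; each planted
    # pair shares an ancestor mutated to the target identity
    seqs = {o: _random_sequence(params.seq_length, rng) for o in ids}
    for a, b, _ratio, sim in params.variant_pairs:
        seqs[b] = _mutate_to_identity(seqs[a], sim, rng)

    annotation = {o: "unrelated" for o in ids}
    clades = ["A3", "C1", "D1", "D1a", "C1-2"]
    for i, cl in enumerate(clades):
        annotation[ids[i]] = cl
    annotation[params.opportunist_otu] = "E-env"
    for k, (a, b, _, _) in enumerate(params.variant_pairs):
        annotation[a] = annotation[b] = f"pairclade{k + 1}"

    table = CountTable(
        otu_ids=ids, sample_ids=samples, counts=counts, otu_annotation=annotation
    )
    truth = {
        "baseline_log_abundance": base.tolist(),
        "class_log2_shift": shift.tolist(),
        "opportunist_otu": params.opportunist_otu,
        "opportunist_log2_shift": params.opportunist_log2_shift,
        "variant_pairs": [list(p) for p in params.variant_pairs],
        "exclusive_high_otus": exclusive,
        "library_sizes": lib.tolist(),
    }
    return table, seqs, truth


def simulate_study(
    seed: int,
    out_dir: str | Path | None = None,
    n_dams_per_pop: int = 4,
    n_sires_per_pop: int = 4,
    n_families: int = 25,
    effect_params: EffectParams | None = None,
    community_params: CommunityParams | None = None,
) -> dict:
    """Run the full generator at study scale and optionally write all files.

    Returns a dict with the design, life-history table, metadata, count
    table, sequences and planted truth.  With ``out_dir`` set, writes
    design.tsv, life_history.tsv, metadata.csv, counts.tsv, otus.fasta and
    truth.json.
    """
    from . import io as rio

    effect_params = effect_params or EffectParams()
    community_params = community_params or CommunityParams()
    rng = np.random.default_rng(seed)
    s_design, s_life, s_meta, s_table = rng.integers(0, 2**31 - 1, size=4)

    design = generate_cross_design(
        n_dams_per_pop, n_sires_per_pop, int(s_design), n_families=n_families
    )
    # The sequencing design is conditional on extreme families existing (the
    # highest- and lowest-mortality families are the ones sequenced), so the
    # outcome draw is repeated deterministically until both classes occur.
    for attempt in range(50):
        life = simulate_life_history(design, effect_params, int(s_life) + attempt)
        fam_classes = assign_mortality_class(life)
        n_cls = fam_classes["mortality_class"].value_counts()
        if n_cls.get("high", 0) >= 2 and n_cls.get("low", 0) >= 2:
            break
    else:
        raise RuntimeError(
            "no outcome draw produced two families per mortality class"
        )
    metadata = make_sequencing_metadata(design, fam_classes, int(s_meta))
    table, seqs, truth = simulate_symbiont_table(
        metadata, community_params, int(s_table)
    )
    truth["effect_params"] = {
        k: v for k, v in vars(effect_params).items()
        if isinstance(v, (int, float))
    }
    truth["seed"] = seed
    result = {
        "design": design,
        "life_history": life,
        "family_classes": fam_classes,
        "metadata": metadata,
        "count_table": table,
        "sequences": seqs,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        design.to_frame().to_csv(out / "design.tsv", sep="\t", index=False)
        rio.write_life_history(life, out / "life_history.tsv")
        rio.write_metadata(metadata, out / "metadata.csv")
        rio.write_count_table(table, out / "counts.tsv")
        rio.write_fasta(seqs, out / "otus.fasta")
        if table.otu_annotation:
            pd.Series(table.otu_annotation, name="clade").rename_axis("otu_id") \
                .to_csv(out / "annotation.tsv", sep="\t")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return result
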