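"""Future-genotype projection under climate change.

Breeds are grouped by the Köppen-Geiger class of their rearing area
(HOT/NOTHOT by summer temperature, DRY/NOTDRY by humidity).  For each
climate-associated SNP, a one-way ANOVA screens whether per-breed allele
frequencies differ between the two groups; a pooled linear regression of
breed allele frequency on the breed's mean value of the associated
environmental variable gives a single regressor b; the future allele
frequency of a group is then

    p_future = clamp(p_current + b * delta, 0, 1),

where delta is the group-mean future-minus-current change of the variable,
and genotype frequencies follow from Hardy-Weinberg (p^2, 2p(1-p),
(1-p)^2).  The model deliberately ignores drift, selection and migration:
it extrapolates the fitted frequency-environment cline only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class KoppenClassError(ValueError):
    pass


#: Köppen-Geiger codes recognised by the grouping step
KNOWN_KOPPEN = frozenset(
    "Af Am Aw As BWh BWk BSh BSk "
    "Csa Csb Csc Cwa Cwb Cwc Cfa Cfb Cfc "
    "Dsa Dsb Dsc Dsd Dwa Dwb Dwc Dwd Dfa Dfb Dfc Dfd "
    "ET EF".split()
)

MACRO_CLASS = {"A": "Tropical", "B": "Arid", "C": "Temperate", "D": "Cold",
               "E": "Polar"}

#: humidity grouping of current classes: dry-summer/steppe vs no-dry-season
DEFAULT_DRY_MAP = {
    "Csa": "DRY", "Csb": "DRY", "BSk": "DRY", "BSh": "DRY",
    "Cfa": "NOTDRY", "Cfb": "NOTDRY", "Dfb": "NOTDRY", "Dfc": "NOTDRY",
    "EF": "NOTDRY",
}

#: classes whose breeds count as HOT (hot-summer temperate climates)
DEFAULT_HOT_CLASSES = frozenset({"Csa", "Cfa"})


def _normalise_class(code: str) -> str:
    code = code.strip()
    for known in KNOWN_KOPPEN:
        if code.lower() == known.lower():
            return known
    return code


def load_koppen_table(path: str | Path | None = None) -> pd.DataFrame:
    """Current and future Köppen class per breed.

    With no path, loads the bundled reference classification for the 32
    georeferenced Italian goat breeds (current climate and the 2070
    projection).
    """
    if path is None:
        src = resources.files("caprascape.data") / "koppen_classes.tsv"
        with resources.as_file(src) as f:
            df = pd.read_csv(f, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    for col in ("current_class", "future_class"):
        df[col] = df[col].map(_normalise_class)
    return df


def load_projection_example() -> pd.DataFrame:
    """Bundled worked-example inputs for one climate-associated SNP."""
    src = resources.files("caprascape.data") / "projection_example.tsv"
    with resources.as_file(src) as f:
        return pd.read_csv(f, sep="\t")


def load_reference_projection_table() -> pd.DataFrame:
    """Bundled reference table of projected genotype frequencies (2-decimal)."""
    src = resources.files("caprascape.data") / "projected_genotype_frequencies.tsv"
    with resources.as_file(src) as f:
        return pd.read_csv(f, sep="\t")


def assign_koppen_groups(
    table: pd.DataFrame,
    dry_map: dict[str, str] | None = None,
    hot_classes: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Attach hot_group and dry_group columns based on the current class."""
    dry_map = dry_map or DEFAULT_DRY_MAP
    hot_classes = hot_classes or DEFAULT_HOT_CLASSES
    out = table.copy()
    hot, dry = [], []
    for _, row in out.iterrows():
        cls = _normalise_class(str(row["current_class"]))
        if cls not in KNOWN_KOPPEN:
            raise KoppenClassError(
                f"breed {row['breed_code']}: unknown Köppen class {cls!r}")
        if cls not in dry_map:
            raise KoppenClassError(
                f"breed {row['breed_code']}: class {cls} absent from the "
                "humidity grouping map")
        hot.append("HOT" if cls in hot_classes else "NOTHOT")
        dry.append(dry_map[cls])
    out["hot_group"] = hot
    out["dry_group"] = dry
    return out


def koppen_change_summary(table: pd.DataFrame) -> dict:
    """Counts of breeds keeping their class, and per macro-class tallies."""
    if len(table) == 0:
        return {"unchanged": 0, "unchanged_breeds": [], "macro_counts": {},
                "unchanged_by_class": {}}
    same = table["current_class"] == table["future_class"]
    macro = table["current_class"].str[0].map(MACRO_CLASS)
    unchanged_by_class = (
        table.loc[same, "current_class"].value_counts().to_dict())
    return {
        "unchanged": int(same.sum()),
        "unchanged_breeds": table.loc[same, "breed_code"].tolist(),
        "macro_counts": macro.value_counts().to_dict(),
        "unchanged_by_class": unchanged_by_class,
    }


def group_anova(values, groups) -> tuple[float, float]:
    """One-way ANOVA F and p for a two-level grouping of breed frequencies."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two levels, got {levels}")
    samples = [values[groups == lv] for lv in levels]
    for lv, s in zip(levels, samples):
        if s.size < 2:
            raise ValueError(f"level {lv!r} has fewer than 2 breeds")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


@dataclass
class RegressionResult:
    b: float           # slope: allele frequency per unit of the variable
    intercept: float
    p_value: float     # slope t-test
    r2: float
    n: int


def climate_regression(env_values, freqs) -> RegressionResult:
    """OLS of per-breed allele frequency on the breed-mean variable value."""
    x = np.asarray(env_values, dtype=float)
    y = np.asarray(freqs, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 breeds")
    if np.var(x) == 0:
        raise ValueError("environmental variable has zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(b=float(res.slope), intercept=float(res.intercept),
                            p_value=float(res.pvalue), r2=float(res.rvalue ** 2),
                            n=int(x.size))


def hwe_genotype_frequencies(p: float) -> tuple[float, float, float]:
    """(homozygote-other, heterozygote, homozygote-focal) under Hardy-Weinberg.

    ``p`` is the frequency of the focal allele; the triple is
    ((1-p)^2, 2p(1-p), p^2) and sums to 1.
    """
    q = 1.0 - p
    return (q * q, 2.0 * p * q, p * p)


@dataclass
class ProjectionRecord:
    snp_id: str
    gene: str
    genotype: str
    group: str
    p_current: float
    p_future: float
    clamped: bool
    current_aa: float   # homozygote for the non-focal allele
    current_het: float
    current_focal: float  # homozygote for the focal allele
    future_aa: float
    future_het: float
    future_focal: float


def project_frequencies(
    p_current: float, b: float, delta: float,
    snp_id: str = "", gene: str = "", genotype: str = "", group: str = "",
) -> ProjectionRecord:
    """Project a group's allele frequency by p + b*delta and expand to HWE.

    ``delta`` is future minus current value of the associated variable
    (group mean); the projected frequency is clamped to [0, 1].
    """
    if not 0.0 <= p_current <= 1.0:
        raise ValueError("p_current outside [0, 1]")
    raw = p_current + b * delta
    p_future = min(max(raw, 0.0), 1.0)
    cur = hwe_genotype_frequencies(p_current)
    fut = hwe_genotype_frequencies(p_future)
    return ProjectionRecord(
        snp_id=snp_id, gene=gene, genotype=genotype, group=group,
        p_current=p_current, p_future=p_future, clamped=(raw != p_future),
        current_aa=cur[0], current_het=cur[1], current_focal=cur[2],
        future_aa=fut[0], future_het=fut[1], future_focal=fut[2],
    )


def projection_table(records: list[ProjectionRecord]) -> pd.DataFrame:
    """Tabulate records in the reference column layout (AA, GG, AG order)."""
    rows = []
    for r in records:
        rows.append({
            "snp_id": r.snp_id, "gene": r.gene, "genotype": r.genotype,
            "group": r.group,
            "AA_current": r.current_aa, "GG_current": r.current_focal,
            "AG_current": r.current_het,
            "AA_future": r.future_aa, "GG_future": r.future_focal,
            "AG_future": r.future_het,
            "p_current": r.p_current, "p_future": r.p_future,
        })
    return pd.DataFrame(rows)


def run_projection(
    hits: pd.DataFrame,
    breed_freqs: pd.DataFrame,
    env_long: pd.DataFrame,
    koppen: pd.DataFrame | None = None,
    grouping: str = "dry",
    anova_alpha: float = 0.05,
    slope_alpha: float = 0.05,
    screen_on: str = "maf",
) -> pd.DataFrame:
    """Full projection stage for association hits.

    ``hits`` needs columns snp_id, genotype, variable (and optionally gene);
    ``breed_freqs`` is breeds x snp_ids focal-allele frequencies;
    ``env_long`` the long env table with current and future epochs;
    ``koppen`` a breed classification table (bundled reference by default).
    Per SNP: ANOVA screen between the two groups (on MAF by default, or the
    focal frequency with ``screen_on="freq"``), pooled OLS regression gate on
    the slope p-value, then per-group projection.
    """
    kop = assign_koppen_groups(koppen if koppen is not None else load_koppen_table())
    group_col = {"dry": "dry_group", "hot": "hot_group"}[grouping]
    kop = kop[kop["breed_code"].isin(breed_freqs.index)]
    groups = kop.set_index("breed_code")[group_col]
    breeds = groups.index.tolist()

    env_cur = env_long[env_long["epoch"] == "current"].pivot(
        index="unit_id", columns="variable", values="value")
    env_fut = env_long[env_long["epoch"] == "future"].pivot(
        index="unit_id", columns="variable", values="value")

    records: list[ProjectionRecord] = []
    seen = set()
    for _, hit in hits.iterrows():
        snp, var = hit["snp_id"], hit["variable"]
        if (snp, var) in seen or snp not in breed_freqs.columns:
            continue
        seen.add((snp, var))
        freqs = breed_freqs.loc[breeds, snp]
        screen = np.minimum(freqs, 1 - freqs) if screen_on == "maf" else freqs
        try:
            _, p_anova = group_anova(screen.to_numpy(), groups.to_numpy())
        except ValueError:
            continue
        if p_anova >= anova_alpha:
            continue
        x = env_cur.loc[breeds, var]
        reg = climate_regression(x.to_numpy(), freqs.to_numpy())
        if reg.p_value >= slope_alpha:
            continue
        delta_all = env_fut.loc[breeds, var] - env_cur.loc[breeds, var]
        for grp in dict.fromkeys(groups):
            members = groups[groups == grp].index
            records.append(project_frequencies(
                p_current=float(freqs.loc[members].mean()),
                b=reg.b,
                delta=float(delta_all.loc[members].mean()),
                snp_id=snp, gene=str(hit.get("gene", "")),
                genotype=str(hit["genotype"]), group=str(grp),
            ))
    return projection_table(records)
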