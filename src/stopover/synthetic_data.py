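"""Synthetic raptor-migration and cloacal-microbiota data with known truth.

Three generators emulate the study system — a spring-migration stopover
bottleneck where buzzards are trapped, measured, swabbed and GPS-tagged:

* :func:`simulate_track` — northbound daily rhumb-line movement from the
  stopover with interleaved stopover days and one of three endpoints
  (arrival at the breeding grounds, death with flatlined accelerometer, or
  abrupt loss of tag connection);
* :func:`simulate_metadata` — sexually dimorphic morphometrics (female mass
  629 ± 77 g, male 518 ± 60 g) with an optional planted capture-date ×
  condition slope;
* :func:`simulate_community` — Dirichlet-multinomial ASV tables over a random
  bifurcating phylogeny, with planted sex-composition shifts, a capture-date
  effect on evenness (via the Dirichlet concentration), a condition-linked
  pathogen-like taxon, and negative-control samples carrying contaminants.

Every generator returns a :class:`GroundTruth` so downstream segmentation,
diversity and differential-abundance stages can be scored against what was
planted.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .community_prep import AsvTable
from .geodesy import in_northern_sector, rhumb_destination
from .morphometrics import assign_age
from .solar import sunrise_sunset

EILAT = (29.55, 34.95)  # the stopover capture site (southern Arava)

RANKS = ["Kingdom", "Phylum", "Class", "Order", "Family", "Genus"]


@dataclasses.dataclass
class GroundTruth:
    """What was planted: day labels, endpoints, effect taxa and slopes."""

    day_labels: dict | None = None  # date -> migratory|stopover
    endpoint: str | None = None
    endpoint_date: dt.date | None = None
    endpoint_location: tuple[float, float] | None = None
    sex_effect_taxa: dict | None = None  # taxon -> log-fold shift (male vs female)
    condition_taxon: str | None = None
    condition_taxon_slope: float = 0.0
    date_evenness_slope: float = 0.0
    condition_date_slope: float = 0.0
    contaminant_taxa: list | None = None
    offender_taxa: list | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.day_labels is not None:
            d["day_labels"] = {k.isoformat(): v for k, v in self.day_labels.items()}
        if self.endpoint_date is not None:
            d["endpoint_date"] = self.endpoint_date.isoformat()
        return json.dumps(d, sort_keys=True, indent=1)


@dataclasses.dataclass
class TrackScenario:
    """One simulated individual's migration plan.

    Migratory days advance ``daily_step_km`` along ``heading_deg`` (northern
    sector) as rhumb-line steps; stopover runs of given lengths are inserted
    after the migratory days listed in ``stopover_after``.  The endpoint is
    ``arrival`` (reverse-turn settling near the end point), ``death``
    (near-zero displacement with flatline accelerometer variance), or
    ``loss`` (abrupt truncation with no behavioural change).
    """

    seed: int = 0
    start_point: tuple[float, float] = EILAT
    start_date: dt.date = dt.date(2019, 4, 10)
    n_migratory_days: int = 8
    stopover_run_lengths: tuple[int, ...] = (2,)
    stopover_after: tuple[int, ...] | None = None  # migratory day indices (1-based)
    daily_step_km: float = 150.0
    heading_deg: float = 15.0
    heading_sd_deg: float = 8.0
    fix_interval_min: float = 30.0
    endpoint: str = "arrival"
    n_post_days: int = 7  # settled days generated after arrival
    n_normal_days_before_end: int | None = None  # for death/loss: days before the event

    def __post_init__(self) -> None:
        if self.daily_step_km <= 40:
            raise ValueError("daily_step_km must exceed 40 km (migratory-day floor)")
        if self.endpoint not in ("arrival", "death", "loss"):
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.endpoint == "arrival" and not in_northern_sector(self.heading_deg):
            raise ValueError("arrival endpoint requires a northern-sector heading")
        if self.stopover_after is None:
            # spread runs through the middle of the migratory stretch
            k = len(self.stopover_run_lengths)
            gaps = np.linspace(1, max(self.n_migratory_days - 1, 1), k + 2)[1:-1]
            self.stopover_after = tuple(int(round(g)) for g in gaps)


def _day_plan(scn: TrackScenario) -> list[str]:
    plan = ["migratory"] * scn.n_migratory_days
    # insert runs back-to-front so earlier indices stay valid
    inserts = sorted(zip(scn.stopover_after, scn.stopover_run_lengths), reverse=True)
    for after, run in inserts:
        pos = min(max(after, 1), scn.n_migratory_days)
        plan[pos:pos] = ["stopover"] * run
    if scn.endpoint == "arrival":
        plan += ["arrival"] + ["post"] * (scn.n_post_days - 1)
    else:
        cut = scn.n_normal_days_before_end
        if cut is not None:
            plan = plan[:cut]
        if scn.endpoint == "death":
            plan += ["dead"] * 3
    return plan


def _day_fix_times(date: dt.date, lat: float, lon: float, interval_min: float):
    rise, set_ = sunrise_sunset(date, lat, lon)
    times = []
    t = rise
    while t <= set_:
        times.append(t)
        t += dt.timedelta(minutes=interval_min)
    return times


def _clip_heading_north(h: float) -> float:
    """Fold a heading into the northern sector, leaving margin at the edges."""
    d = (h + 180.0) % 360.0 - 180.0  # signed deviation from north
    return float(np.clip(d, -75.0, 75.0)) % 360.0


def simulate_track(scenario: TrackScenario) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one individual's GPS fixes (with ACC variance) and truth.

    Fixes are emitted between local sunrise and sunset at the scenario's fix
    interval.  Migratory days land exactly ``daily_step_km`` from the roost
    (the daily beeline), with lateral jitter on intermediate fixes so the
    within-day path is at least the beeline.  Stopover/settled days wander
    with displacement well under the 19-km migratory-day floor.
    """
    rng = np.random.default_rng(scenario.seed)
    plan = _day_plan(scenario)
    lat, lon = scenario.start_point
    rows: list[tuple] = []
    labels: dict[dt.date, str] = {}
    truth = GroundTruth(day_labels=labels, endpoint=scenario.endpoint)
    prev_heading = scenario.heading_deg
    ind = f"bird{scenario.seed:04d}"
    for i, kind in enumerate(plan):
        date = scenario.start_date + dt.timedelta(days=i)
        times = _day_fix_times(date, lat, lon, scenario.fix_interval_min)
        n = len(times)
        if kind == "migratory":
            step = scenario.daily_step_km * float(rng.uniform(0.9, 1.15))
            heading = _clip_heading_north(
                scenario.heading_deg + float(rng.normal(0.0, scenario.heading_sd_deg))
            )
            prev_heading = heading
            acc = rng.uniform(0.5, 1.5, size=n)
            jitter = 1.0
        elif kind in ("stopover", "post"):
            step = float(rng.uniform(0.5, 8.0))
            heading = float(rng.uniform(0.0, 360.0))
            acc = rng.uniform(0.2, 0.6, size=n)
            jitter = 0.25
        elif kind == "arrival":
            step = float(rng.uniform(1.0, 6.0))
            heading = (prev_heading + 180.0 + float(rng.normal(0.0, 20.0))) % 360.0
            acc = rng.uniform(0.2, 0.6, size=n)
            jitter = 0.25
        else:  # dead
            step = 0.0
            heading = 0.0
            acc = rng.uniform(0.0, 0.005, size=n)
            jitter = 0.0
        frac = np.linspace(0.0, 1.0, n)
        day_lat, day_lon = rhumb_destination(lat, lon, heading, step * frac)
        day_lat, day_lon = np.atleast_1d(day_lat), np.atleast_1d(day_lon)
        if jitter > 0 and n > 2:
            off = rng.normal(0.0, jitter, size=n - 2)
            jl, jg = rhumb_destination(
                day_lat[1:-1], day_lon[1:-1], (heading + 90.0) % 360.0, off
            )
            day_lat[1:-1], day_lon[1:-1] = jl, jg
        elif kind == "dead" and n > 0:
            jl, jg = rhumb_destination(
                day_lat, day_lon, rng.uniform(0, 360, size=n), rng.uniform(0, 0.02, size=n)
            )
            day_lat, day_lon = jl, jg
        for t, la, lo, a in zip(times, day_lat, day_lon, acc):
            rows.append((ind, t, float(la), float(lo), float(a)))
        labels[date] = "migratory" if kind == "migratory" else "stopover"
        if kind != "dead":
            lat, lon = float(day_lat[-1]), float(day_lon[-1])
        if kind == "arrival":
            truth.endpoint_date = date
            truth.endpoint_location = (lat, lon)
        if kind == "dead" and truth.endpoint_date is None:
            truth.endpoint_date = date
            truth.endpoint_location = (lat, lon)
    if scenario.endpoint == "loss":
        last_date = scenario.start_date + dt.timedelta(days=len(plan) - 1)
        truth.endpoint_date = last_date
        truth.endpoint_location = None
    fixes = pd.DataFrame(rows, columns=["individual_id", "timestamp", "lat", "lon", "acc_var"])
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
    return fixes, truth


def simulate_metadata(
    n_females: int,
    n_males: int,
    seed: int = 0,
    condition_date_slope: float = 0.0,
) -> pd.DataFrame:
    """Morphometric metadata for a trapped cohort.

    Wing lengths are drawn per sex and mass follows an allometric power law
    (mass ∝ wing²) with lognormal noise, calibrated to the observed sexual
    dimorphism (females 629 ± 77 g, males 518 ± 60 g).  A nonzero
    ``condition_date_slope`` (grams per Julian day) plants a linear trend of
    mass residual on capture date.
    """
    if n_females < 0 or n_males < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    params = {
        "female": (n_females, 380.0, 11.0, 0.105, 629.0, "F"),
        "male": (n_males, 355.0, 10.0, 0.099, 518.0, "M"),
    }
    date_lo, date_hi = 91, 120  # April, Julian days
    date_mid = (date_lo + date_hi) / 2.0
    for sex, (n, wing_mu, wing_sd, sigma, mass_mu, prefix) in params.items():
        if n == 0:
            continue
        wing = rng.normal(wing_mu, wing_sd, size=n)
        eps = rng.normal(0.0, sigma, size=n)
        # c calibrated so E[mass] = mass_mu under the lognormal noise
        c = mass_mu / ((wing_mu**2 + wing_sd**2) * np.exp(sigma**2 / 2.0))
        mass = c * wing**2 * np.exp(eps)
        date = rng.integers(date_lo, date_hi + 1, size=n)
        mass = mass + condition_date_slope * (date - date_mid)
        euring = np.where(rng.random(n) < 0.45, 5, rng.integers(6, 9, size=n))
        for i in range(n):
            rows.append(
                {
                    "id": f"{prefix}{i + 1:03d}",
                    "sex": sex,
                    "euring_age": int(euring[i]),
                    "age_class": assign_age(int(euring[i])),
                    "mass_g": float(mass[i]),
                    "wing_mm": float(wing[i]),
                    "capture_date": int(date[i]),
                    "sample_id": f"{prefix}{i + 1:03d}",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "sex",
            "euring_age",
            "age_class",
            "mass_g",
            "wing_mm",
            "capture_date",
            "sample_id",
        ],
    )


@dataclasses.dataclass
class CommunityScenario:
    """Dirichlet-multinomial community generator settings.

    ``dispersion`` is the Dirichlet concentration (lower = more overdispersed
    draws, lower expected evenness); ``date_evenness_slope`` scales the
    concentration as exp(slope · (date − mean date)), so a negative slope
    plants declining Shannon diversity with later capture; ``sex_effect_taxa``
    maps taxa to log-fold shifts applied to males; the designated
    ``condition_taxon`` shifts by ``condition_taxon_slope`` per standardized
    unit of body condition (pathogen-like when negative).
    """

    seed: int = 0
    n_samples: int = 54
    n_taxa: int = 150
    base_log_abundance: np.ndarray | None = None
    dispersion: float = 50.0
    sex_effect_taxa: dict[str, float] = dataclasses.field(default_factory=dict)
    date_evenness_slope: float = 0.0
    condition_taxon: str | None = None
    condition_taxon_slope: float = 0.0
    depth_range: tuple[int, int] = (14523, 76393)
    n_controls: int = 3
    contaminant_taxa: tuple[str, ...] | None = None
    n_contaminants: int = 5
    n_offenders: int = 0  # non-bacterial / chloroplast / unresolved-phylum taxa

    def __post_init__(self) -> None:
        if self.depth_range[0] < 1:
            raise ValueError("depths must be >= 1")
        if self.n_taxa < 1:
            raise ValueError("need at least one taxon")


def _taxon_ids(n: int) -> list[str]:
    return [f"ASV{i + 1:04d}" for i in range(n)]


def _random_tree_newick(taxa: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating rooted tree with positive branch lengths."""
    nodes = [f"{t}:{rng.exponential(1.0) + 0.05:.6f}" for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(1.0) + 0.05:.6f}")
    inner = nodes[0]
    # strip the root's branch length
    return f"{inner.rsplit(':', 1)[0]};" if len(taxa) > 1 else f"({inner});"


def _taxonomy(taxa: list[str], contaminants: list[str], offenders: list[str],
              condition_taxon: str | None, rng: np.random.Generator) -> pd.DataFrame:
    phyla = [
        "Firmicutes",
        "Actinobacteriota",
        "Proteobacteria",
        "Bacteroidota",
        "Fusobacteriota",
        "Synergistota",
    ]
    rows = []
    genus_size = 3
    for i, t in enumerate(taxa):
        p = phyla[int(rng.integers(len(phyla)))]
        g = f"Genus{i // genus_size + 1:04d}"
        row = {
            "taxon_id": t,
            "Kingdom": "Bacteria",
            "Phylum": p,
            "Class": f"{p}_c",
            "Order": f"{p}_o",
            "Family": f"{p}_f",
            "Genus": g,
        }
        if t == condition_taxon:
            row.update(Phylum="Proteobacteria", Genus="Escherichia-Shigella")
        if t in contaminants:
            row["Genus"] = f"Contaminant{contaminants.index(t) + 1}"
        rows.append(row)
    # offenders: one chloroplast, one mitochondria, rest unresolved or non-bacterial
    for k, t in enumerate(offenders):
        kind = k % 4
        row = {
            "taxon_id": t,
            "Kingdom": "Bacteria",
            "Phylum": "Cyanobacteria",
            "Class": "c",
            "Order": "o",
            "Family": "f",
            "Genus": f"Off{k + 1}",
        }
        if kind == 0:
            row.update(Order="Chloroplast")
        elif kind == 1:
            row.update(Family="Mitochondria")
        elif kind == 2:
            row.update(Kingdom="Eukaryota")
        else:
            row.update(Phylum="")
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon_id")


def simulate_community(
    scenario: CommunityScenario, metadata: pd.DataFrame
) -> tuple[AsvTable, pd.DataFrame, str, GroundTruth]:
    """Draw the ASV table, taxonomy, Newick phylogeny and ground truth.

    One sample per metadata row plus ``n_controls`` negative controls.
    Planted effects act on per-sample log abundances before the softmax
    normalization; counts are Dirichlet-multinomial at a depth drawn
    uniformly from ``depth_range``.
    """
    if scenario.n_samples != len(metadata):
        raise ValueError("n_samples must equal the number of metadata rows")
    rng = np.random.default_rng(scenario.seed)
    taxa = _taxon_ids(scenario.n_taxa)
    if scenario.contaminant_taxa is None:
        contaminants = taxa[-scenario.n_contaminants:] if scenario.n_contaminants else []
    else:
        contaminants = list(scenario.contaminant_taxa)
    for t in list(scenario.sex_effect_taxa) + list(contaminants) + (
        [scenario.condition_taxon] if scenario.condition_taxon else []
    ):
        if t not in taxa:
            raise ValueError(f"effect taxon {t!r} not in the taxon set")
    offenders = [f"OFF{i + 1:03d}" for i in range(scenario.n_offenders)]
    all_taxa = taxa + offenders
    if scenario.base_log_abundance is None:
        base = rng.normal(0.0, 2.0, size=scenario.n_taxa)
    else:
        base = np.asarray(scenario.base_log_abundance, dtype=float)
        if base.shape != (scenario.n_taxa,):
            raise ValueError("base_log_abundance length mismatch")
    base = base.copy()
    cont_idx = [taxa.index(t) for t in contaminants]
    base[cont_idx] = -6.0  # contaminants are rare in true samples

    dates = metadata["capture_date"].to_numpy(dtype=float)
    date_z = dates - dates.mean()
    cond_col = "smi_g" if "smi_g" in metadata.columns else "mass_g"
    cond = metadata[cond_col].to_numpy(dtype=float).copy()
    for sex in metadata["sex"].unique():
        m = (metadata["sex"] == sex).to_numpy()
        sd = cond[m].std(ddof=0)
        cond[m] = (cond[m] - cond[m].mean()) / (sd if sd > 0 else 1.0)
    is_male = (metadata["sex"] == "male").to_numpy()

    counts = np.zeros((scenario.n_samples + scenario.n_controls, len(all_taxa)), dtype=int)
    sample_ids = list(metadata["sample_id"].astype(str))
    for s in range(scenario.n_samples):
        la = base.copy()
        if is_male[s]:
            for t, lfc in scenario.sex_effect_taxa.items():
                la[taxa.index(t)] += lfc
        if scenario.condition_taxon is not None:
            la[taxa.index(scenario.condition_taxon)] += scenario.condition_taxon_slope * cond[s]
        if scenario.n_offenders:
            la = np.concatenate([la, rng.normal(-3.0, 1.0, size=scenario.n_offenders)])
        p = np.exp(la - la.max())
        p /= p.sum()
        theta = scenario.dispersion * float(np.exp(scenario.date_evenness_slope * date_z[s]))
        q = rng.dirichlet(np.maximum(theta * p, 1e-8))
        depth = int(rng.integers(scenario.depth_range[0], scenario.depth_range[1] + 1))
        counts[s] = rng.multinomial(depth, q)
    # negative controls: dominated by contaminants, faint cross-talk of real taxa
    for c in range(scenario.n_controls):
        la = np.full(len(all_taxa), -7.0)
        la[: scenario.n_taxa] += rng.normal(0.0, 0.5, size=scenario.n_taxa)
        for i in cont_idx:
            la[i] = rng.normal(3.0, 0.3)
        p = np.exp(la - la.max())
        p /= p.sum()
        q = rng.dirichlet(np.maximum(scenario.dispersion * p, 1e-8))
        depth = int(rng.integers(scenario.depth_range[0], scenario.depth_range[1] + 1))
        row = rng.multinomial(depth, q)
        row[cont_idx] = np.maximum(row[cont_idx], 1)  # contaminants planted deterministically
        counts[scenario.n_samples + c] = row
        sample_ids.append(f"CTRL{c + 1}")

    count_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=all_taxa)
    is_control = pd.Series(
        [False] * scenario.n_samples + [True] * scenario.n_controls, index=count_df.index
    )
    taxonomy = _taxonomy(taxa, contaminants, offenders, scenario.condition_taxon, rng)
    newick = _random_tree_newick(all_taxa, rng)
    truth = GroundTruth(
        sex_effect_taxa=dict(scenario.sex_effect_taxa),
        condition_taxon=scenario.condition_taxon,
        condition_taxon_slope=scenario.condition_taxon_slope,
        date_evenness_slope=scenario.date_evenness_slope,
        contaminant_taxa=contaminants,
        offender_taxa=offenders,
    )
    table = AsvTable(counts=count_df, taxonomy=taxonomy, is_control=is_control)
    return table, taxonomy, newick, truth


def write_dataset(
    outdir,
    fixes: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    table: AsvTable | None = None,
    newick: str | None = None,
    truth: GroundTruth | None = None,
) -> None:
    """Write generated artifacts as plain-text files (CSV/TSV/Newick/JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fixes is not None:
        out = fixes.copy()
        out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
        out.to_csv(outdir / "gps_fixes.csv", index=False)
    if metadata is not None:
        metadata.to_csv(outdir / "metadata.csv", index=False)
    if table is not None:
        table.counts.to_csv(outdir / "asv_table.tsv", sep="\t")
        table.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
        table.is_control.rename("is_control").to_csv(outdir / "controls.tsv", sep="\t")
    if newick is not None:
        (outdir / "tree.nwk").write_text(newick + "\n")
    if truth is not None:
        (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
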