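"""Full-analysis orchestration: one config in, one machine-readable report out.

Runs richness -> MDE null model -> ancestral reconstruction ->
colonization -> diversification rates -> Rapoport profiles -> regressions /
variance partitioning, and assembles a single JSON-serializable report
(with CSV mirrors of the tabular sections).  Reports are bit-reproducible
from (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colonization import colonization_summary, edge_colonizations
from .core_io import (
    ElevationGrid,
    ElevgradError,
    make_grid,
    read_band_climate,
    read_occurrences,
    read_species_ranges,
    read_tree,
)
from .divrate import DEFAULT_EPSILONS, clade_rate_table, default_clades
from .mde import DEFAULT_REPS, simulate_mde
from .phylo import node_ranges
from .rapoport import cross_species_table, stevens_profile
from .richness import interpolate_richness, observed_richness
from .stats import ols_regress, variance_partition3, vif_screen

logger = logging.getLogger("elevgrad")

#: Default polynomial degree per analysis (richness~MAT and range-size~AP
#: are unimodal, hence quadratic; everything else linear).
DEFAULT_DEGREES = {"richness~MAT": 2, "range_size~AP": 2}

CLIMATE_PREDICTORS = ("MAT", "MDR", "TS", "AP", "PS", "PDQ")
AREA_PREDICTORS = ("area_river", "area_total")


def _jsonify(obj):
    """Recursively convert numpy scalars/arrays and NaN for stable JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _reg_entry(res) -> dict:
    return {
        "response": res.response,
        "predictors": list(res.predictors),
        "degree": res.degree,
        "standardized": res.standardized,
        "n": res.n,
        "r2": res.r2,
        "adj_r2": res.adj_r2,
        "f_pvalue": res.f_pvalue,
        "resid_se": res.resid_se,
        "df_resid": res.df_resid,
        "coefficients": {
            term: {
                "estimate": row["estimate"],
                "se": row["se"],
                "t": row["t"],
                "p": row["p"],
            }
            for term, row in res.params.iterrows()
        },
        "vif": res.vif,
    }


def analyze(
    grid: ElevationGrid,
    ranges,
    records=None,
    tree=None,
    climate: pd.DataFrame | None = None,
    clades=None,
    reps: int = DEFAULT_REPS,
    seed: int = 0,
    epsilons=DEFAULT_EPSILONS,
    event_age: str = "interp",
    degrees: dict | None = None,
    skip_phylo: bool = False,
) -> dict:
    """Run every stage on in-memory inputs and return the report dict.

    ``tree=None`` or ``skip_phylo`` omits the colonization/diversification
    sections and the regressions that depend on them.
    """
    degrees = {**DEFAULT_DEGREES, **(degrees or {})}
    report: dict = {
        "software": {"name": "elevgrad", "version": __version__},
        "config": {
            "grid": {
                "domain_lo": grid.domain_lo,
                "domain_hi": grid.domain_hi,
                "band_width": grid.band_width,
                "n_bands": grid.n_bands,
            },
            "reps": reps,
            "seed": seed,
            "epsilons": list(epsilons),
            "event_age": event_age,
            "degrees": degrees,
            "skip_phylo": bool(skip_phylo or tree is None),
        },
    }

    # --- richness ----------------------------------------------------
    interp = interpolate_richness(ranges, grid)
    report["richness"] = {
        "interpolated": interp.counts,
        "band_lo": grid.band_edges[:-1],
        "band_midpoint": grid.band_midpoints,
    }
    if records is not None:
        report["richness"]["observed"] = observed_richness(records, grid).counts

    # --- MDE null model ----------------------------------------------
    mde_res = simulate_mde(ranges, grid, reps=reps, seed=seed)
    report["mde"] = {
        "mean_richness": mde_res.mean_richness,
        "ci_lo": mde_res.ci_lo,
        "ci_hi": mde_res.ci_hi,
        "reps": mde_res.reps,
        "seed": mde_res.seed,
    }

    # --- phylogenetic stages -----------------------------------------
    colsum = None
    if tree is not None and not skip_phylo:
        nodes = node_ranges(tree, ranges)
        report["node_ranges"] = {
            n: {"midpoint": v.midpoint, "size": v.size, "lo": v.lo,
                "hi": v.hi, "age": v.age}
            for n, v in sorted(nodes.items())
        }
        events = edge_colonizations(tree, nodes, grid, event_age=event_age)
        colsum = colonization_summary(events, grid)
        report["colonization"] = {
            "events": [
                {"band": e.band, "edge": e.edge, "age": e.age} for e in events
            ],
            "frequency": colsum.frequency,
            "oldest_age": colsum.oldest_age,
            "summed_age": colsum.summed_age,
            "average_age": colsum.average_age,
        }
        clade_map = clades if clades is not None else default_clades(tree)
        rate_rows = clade_rate_table(tree, clade_map, ranges, nodes, epsilons)
        report["diversification"] = [
            {
                "clade": r.clade,
                "n": r.n,
                "t_stem": r.t_stem,
                "t_crown": r.t_crown,
                "rates_stem": {str(k): v for k, v in r.rates_stem.items()},
                "rates_crown": {str(k): v for k, v in r.rates_crown.items()},
                "mean_elevation": r.mean_elevation,
                "ancestral_elevation": r.ancestral_elevation,
            }
            for r in rate_rows
        ]

    # --- Rapoport ------------------------------------------------------
    stevens = stevens_profile(ranges, grid)
    report["rapoport"] = {
        "stevens_mean_range_size": stevens.mean_range_size,
        "stevens_species_count": stevens.species_count,
        "cross_species": [
            {"species": r.species, "midpoint": m, "size": s}
            for r, (m, s) in zip(ranges, cross_species_table(ranges))
        ],
    }

    # --- band table for the regression layer --------------------------
    band = pd.DataFrame(
        {
            "band_midpoint": grid.band_midpoints,
            "richness": interp.counts.astype(float),
            "mde_mean": mde_res.mean_richness,
            "stevens_size": stevens.mean_range_size,
        },
        index=pd.RangeIndex(grid.n_bands, name="band"),
    )
    if climate is not None:
        band = band.join(climate.astype(float))
    if colsum is not None:
        band["oldest_age"] = colsum.oldest_age
        band["summed_age"] = colsum.summed_age
        band["average_age"] = colsum.average_age
        band["frequency"] = colsum.frequency.astype(float)
    report["band_table"] = {c: band[c].to_numpy() for c in band.columns}

    # --- regressions ---------------------------------------------------
    regs: dict[str, dict] = {}

    def simple(name, y, xcol, default_degree=1):
        deg = int(degrees.get(name, default_degree))
        try:
            regs[name] = _reg_entry(
                ols_regress(y, band[[xcol]], degree=deg, response=name.split("~")[0])
            )
        except ElevgradError as err:
            logger.warning("regression %s skipped: %s", name, err)

    climate_cols = [c for c in CLIMATE_PREDICTORS + AREA_PREDICTORS
                    if c in band.columns]
    for c in climate_cols:
        simple(f"richness~{c}", band["richness"], c)
    simple("richness~MDE", band["richness"], "mde_mean")
    if colsum is not None:
        for c in ("oldest_age", "summed_age", "average_age", "frequency"):
            simple(f"richness~{c}", band["richness"], c)

    # Rapoport trend tests
    simple("stevens_size~elevation", band["stevens_size"], "band_midpoint")
    cross = pd.DataFrame(cross_species_table(ranges), columns=["midpoint", "size"])
    regs["cross_species_size~midpoint"] = _reg_entry(
        ols_regress(cross["size"], cross[["midpoint"]], response="size")
    )

    # range size vs climate (band-level, per the climatic variability test)
    for c in [c for c in CLIMATE_PREDICTORS if c in band.columns]:
        simple(f"range_size~{c}", band["stevens_size"], c)
    if {"MDR", "PS", "PDQ"} <= set(band.columns):
        regs["range_size~MDR+PS+PDQ"] = _reg_entry(
            ols_regress(band["stevens_size"], band[["MDR", "PS", "PDQ"]],
                        standardize=True, response="range_size")
        )
        regs["range_size~MDR+PS"] = _reg_entry(
            ols_regress(band["stevens_size"], band[["MDR", "PS"]],
                        standardize=True, response="range_size")
        )

    # VIF-screened multiple regression of richness on all predictors
    candidates = climate_cols + ["mde_mean"]
    if colsum is not None:
        candidates += ["summed_age", "frequency"]
    X = band[candidates].dropna()
    if len(candidates) >= 2 and len(X) > len(candidates) + 2:
        retained, vifs = vif_screen(X, threshold=3.0)
        res = ols_regress(
            band.loc[X.index, "richness"], X[retained], standardize=True,
            response="richness",
        )
        regs["richness~multiple(VIF<3)"] = _reg_entry(res)
        regs["richness~multiple(VIF<3)"]["screened_out"] = sorted(
            set(candidates) - set(retained)
        )

    # diversification-rate regressions (montane species pump test)
    if colsum is not None and report.get("diversification"):
        dr = pd.DataFrame(
            [
                {
                    "rate": row["rates_crown"].get("0.45"),
                    "mean_elevation": row["mean_elevation"],
                    "ancestral_elevation": row["ancestral_elevation"],
                }
                for row in report["diversification"]
                if row["rates_crown"].get("0.45") is not None
            ]
        )
        if len(dr) >= 4:
            for xcol in ("mean_elevation", "ancestral_elevation"):
                regs[f"divrate~{xcol}"] = _reg_entry(
                    ols_regress(dr["rate"], dr[[xcol]], response="divrate")
                )

    report["regressions"] = regs

    # --- variance partitioning (MAT / MDE / SAC) -----------------------
    if colsum is not None and "MAT" in band.columns:
        vp = variance_partition3(
            band["richness"],
            band[["MAT"]],
            band[["mde_mean"]],
            band[["summed_age"]],
            labels=("MAT", "MDE", "SAC"),
        )
        report["variance_partition"] = {
            "labels": list(vp.labels),
            "a": vp.a, "b": vp.b, "c": vp.c, "d": vp.d, "e": vp.e,
            "f": vp.f, "g": vp.g, "h": vp.h,
            "explained": vp.explained,
            "truncated": vp.truncated,
        }

    return _jsonify(report)


def run_full_analysis(config: dict, out_dir=None) -> dict:
    """File-facing wrapper: load the inputs named in ``config`` and analyze.

    Config keys: ``inputs`` (ranges, and optionally records/tree/climate/
    clades paths), ``grid`` (domain_lo, domain_hi, band_width), ``reps``,
    ``seed``, ``epsilons``, ``event_age``, ``degrees``, ``skip_phylo``.
    When ``out_dir`` is given, writes report.json plus CSV mirrors.
    """
    inputs = config.get("inputs", {})
    if "ranges" not in inputs:
        raise ElevgradError("config.inputs.ranges is required")
    g = config.get("grid", {})
    grid = make_grid(
        g.get("domain_lo", 600), g.get("domain_hi", 4300), g.get("band_width", 200)
    )
    ranges = read_species_ranges(inputs["ranges"])
    records = read_occurrences(inputs["records"]) if inputs.get("records") else None
    tree = read_tree(inputs["tree"]) if inputs.get("tree") else None
    climate = (
        read_band_climate(inputs["climate"], grid) if inputs.get("climate") else None
    )
    clades = None
    if inputs.get("clades"):
        df = pd.read_csv(inputs["clades"])
        clades = {
            str(name): set(map(str, grp["species"]))
            for name, grp in df.groupby("clade")
        }

    report = analyze(
        grid,
        ranges,
        records=records,
        tree=tree,
        climate=climate,
        clades=clades,
        reps=int(config.get("reps", DEFAULT_REPS)),
        seed=int(config.get("seed", 0)),
        epsilons=tuple(config.get("epsilons", DEFAULT_EPSILONS)),
        event_age=config.get("event_age", "interp"),
        degrees=config.get("degrees"),
        skip_phylo=bool(config.get("skip_phylo", False)),
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: dict, out_dir) -> None:
    """Write report.json plus CSV mirrors of the tabular sections."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    band = pd.DataFrame(report["band_table"])
    band.index.name = "band"
    band.to_csv(out / "band_table.csv")
    regs = report.get("regressions", {})
    if regs:
        pd.DataFrame(
            [
                {
                    "analysis": name,
                    "degree": r["degree"],
                    "n": r["n"],
                    "r2": r["r2"],
                    "adj_r2": r["adj_r2"],
                    "f_pvalue": r["f_pvalue"],
                }
                for name, r in sorted(regs.items())
            ]
        ).to_csv(out / "regressions.csv", index=False)
    if report.get("diversification"):
        rows = []
        for row in report["diversification"]:
            flat = {k: row[k] for k in
                    ("clade", "n", "t_stem", "t_crown", "mean_elevation",
                     "ancestral_elevation")}
            for eps, v in row["rates_stem"].items():
                flat[f"r_stem_eps{eps}"] = v
            for eps, v in row["rates_crown"].items():
                flat[f"r_crown_eps{eps}"] = v
            rows.append(flat)
        pd.DataFrame(rows).to_csv(out / "clade_rates.csv", index=False)
    if report.get("colonization"):
        pd.DataFrame(report["colonization"]["events"]).to_csv(
            out / "colonization_events.csv", index=False
        )
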