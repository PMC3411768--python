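"""End-to-end orchestration: simulate -> restrict -> normalize -> noise
filter -> binning -> transforms -> diversity / ordination / performance.

Every stage writes its artifact into the run directory; a manifest of
SHA-256 hashes makes byte-level reproducibility checkable (identical config
and master seed imply an identical manifest).  Per-stage seeds are derived
from the master seed by stage name, so toggling one stage never shifts the
randomness of another.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alpha, beta, binning, io, ordination, peaks, performance, reference
from .synthetic import SimulationConfig

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "bin", "diversity", "betadiv", "cca", "performance")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master_seed ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    peak_table_path: str | None = None      # use existing data instead of simulating
    operational_path: str | None = None
    marker_range: tuple = (50.0, 700.0)
    k_sigma: float = 3.0
    center: str = "median"
    apply_peaks_filter: bool = True
    width_table: tuple = binning.DEFAULT_WIDTH_TABLE
    nmds_dims: int = 3
    nmds_restarts: int = 110
    n_perm_community: int = 999
    n_perm_cca: int = 999
    cca_scheme: str = "unrestricted"
    simper_cutoff: float = 0.25
    seed: int = 0
    out_dir: str = "trflpipe_run"

    def to_yaml(self, path) -> None:
        data = asdict(self)
        # the output location is where the file already sits; leaving it out
        # keeps serialized configs (and hence manifests) location-independent
        data.pop("out_dir", None)
        data["width_table"] = [list(w) for w in self.width_table]
        data["marker_range"] = list(self.marker_range)
        sim = data["simulation"]
        sim["enzymes"] = list(sim["enzymes"])
        sim["size_range"] = list(sim["size_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        sim = data.get("simulation", {})
        if sim:
            sim["plants"] = sim.get("plants", [])
            sim["enzymes"] = tuple(sim.get("enzymes", ()))
            sim["size_range"] = tuple(sim.get("size_range", (50.0, 700.0)))
            from .synthetic import PlantSpec
            sim["plants"] = [
                p if isinstance(p, PlantSpec) else PlantSpec(**p) for p in sim["plants"]
            ]
            data["simulation"] = SimulationConfig(**sim)
        data["width_table"] = tuple(
            tuple(w) for w in data.get("width_table", binning.DEFAULT_WIDTH_TABLE)
        )
        data["marker_range"] = tuple(data.get("marker_range", (50.0, 700.0)))
        return cls(**data)

    @classmethod
    def demo(cls, out_dir: str = "trflpipe_demo", seed: int = 0) -> "RunConfig":
        """The bundled demonstration run: the default study conditions."""
        sim = SimulationConfig(seed=stage_seed(seed, "simulate"))
        return cls(simulation=sim, seed=seed, out_dir=out_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a dict of results plus manifest.

    Any stage failure aborts with the failing stage named; artifacts written
    before the failure are retained in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    results: dict = {}
    stage = "init"
    try:
        # ------------------------------------------------ simulate / load
        stage = "simulate"
        from . import synthetic
        if config.peak_table_path:
            table = io.read_peak_table(config.peak_table_path)
            ops = pd.read_csv(config.operational_path)
        else:
            sim = config.simulation
            table = synthetic.simulate_peak_tables(sim)
            ops = synthetic.simulate_operational_table(sim)
        io.write_peak_table(table, out / "peaks_raw.tsv")
        ops.to_csv(out / "operational.csv", index=False)
        meta = table[["sample_id", "plant", "month"]].drop_duplicates()
        logger.info("simulate: %d peaks, %d samples", len(table), meta.shape[0])

        # ------------------------------------------------ restrict + normalize
        stage = "filter"
        restricted = io.restrict_to_marker_range(table, *config.marker_range)
        profiles = io.normalize_profiles(restricted)
        if config.apply_peaks_filter:
            filt = peaks.filter_profiles(
                profiles, k_sigma=config.k_sigma, center=config.center
            )
            kept_profiles = [f.retained for f in filt if len(f.retained)]
            thresholds = pd.DataFrame([
                {
                    "sample_id": f.sample_id, "enzyme": f.enzyme,
                    "threshold": f.threshold, "n_iterations": f.n_iterations,
                    "n_input": f.n_input, "n_removed": f.n_removed,
                    "flag": f.flag or "",
                }
                for f in filt
            ])
            thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
            logger.info(
                "filter: %d/%d peaks retained over %d profiles",
                sum(len(p) for p in kept_profiles),
                sum(f.n_input for f in filt), len(filt),
            )
        else:
            kept_profiles = profiles
        io.write_peak_table(
            io.profiles_to_table(kept_profiles, meta), out / "peaks_filtered.tsv"
        )

        # ------------------------------------------------ binning
        stage = "bin"
        sample_ids = sorted(meta["sample_id"])
        matrices: dict[str, pd.DataFrame] = {}
        audits = []
        enzymes = sorted({p.enzyme for p in kept_profiles})
        for enzyme in enzymes:
            profs = [p for p in kept_profiles if p.enzyme == enzyme]
            m, bins = binning.bin_enzyme(profs, config.width_table, sample_ids)
            matrices[enzyme] = m
            io.write_matrix(m, out / f"matrix_{enzyme}.tsv")
            a = binning.audit_table(bins)
            a.insert(0, "enzyme", enzyme)
            audits.append(a)
        pd.concat(audits, ignore_index=True).to_csv(
            out / "bin_audit.tsv", sep="\t", index=False
        )
        combined = beta.concat_enzyme_matrices(matrices)
        io.write_matrix(combined, out / "matrix_combined.tsv")
        results["matrices"] = matrices
        results["combined"] = combined

        sample_meta = meta.set_index("sample_id").loc[combined.index]
        grouping = sample_meta["plant"]

        # ------------------------------------------------ beta diversity
        stage = "betadiv"
        sqrt_combined = io.sqrt_transform(combined)
        dm = beta.bray_curtis(sqrt_combined)
        pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        nmds_res = beta.nmds(
            dm, k=config.nmds_dims, restarts=config.nmds_restarts,
            seed=stage_seed(config.seed, "nmds"),
        )
        nmds_res.coordinates.to_csv(out / "nmds_coordinates.tsv", sep="\t")
        anosim_res = beta.anosim(
            dm, grouping, n_perm=config.n_perm_community,
            seed=stage_seed(config.seed, "anosim"),
        )
        npmanova_res = beta.npmanova(
            dm, grouping, n_perm=config.n_perm_community,
            seed=stage_seed(config.seed, "npmanova"),
        )
        simper_table = beta.simper(sqrt_combined, grouping, config.simper_cutoff)
        simper_table.to_csv(out / "simper.tsv", sep="\t", index=False)
        _write_json(
            {
                "nmds_stress": nmds_res.stress,
                "nmds_dims": nmds_res.k,
                "nmds_restarts": nmds_res.n_restarts,
                "anosim_R": anosim_res.statistic,
                "anosim_p": anosim_res.p_value,
                "npmanova_F": npmanova_res.statistic,
                "npmanova_p": npmanova_res.p_value,
                "simper_mean_dissimilarity":
                    simper_table.attrs["mean_between_group_dissimilarity"],
            },
            out / "beta_summary.json",
        )
        results.update(nmds=nmds_res, anosim=anosim_res, npmanova=npmanova_res,
                       simper=simper_table)
        logger.info("betadiv: stress=%.4f R=%.4f F=%.3f",
                    nmds_res.stress, anosim_res.statistic, npmanova_res.statistic)

        # ------------------------------------------------ alpha diversity
        stage = "diversity"
        rich_rows = []
        for enzyme, m in matrices.items():
            r = alpha.richness(m)
            for sid, val in r.items():
                rich_rows.append({
                    "sample_id": sid, "enzyme": enzyme,
                    "plant": sample_meta.loc[sid, "plant"],
                    "month": int(sample_meta.loc[sid, "month"]),
                    "richness": int(val),
                })
        rich = pd.DataFrame(rich_rows).sort_values(
            ["enzyme", "plant", "month"]).reset_index(drop=True)
        rich.to_csv(out / "richness.tsv", sep="\t", index=False)
        plants = sorted(rich["plant"].unique())
        paired = None
        if len(plants) == 2:
            wide = rich.pivot_table(index=["month", "enzyme"], columns="plant",
                                    values="richness")
            wide = wide.dropna()
            paired = alpha.paired_richness_test(wide[plants[0]], wide[plants[1]])
        renyi = alpha.group_renyi(combined, grouping)
        renyi_df = pd.DataFrame(
            {name: prof.values for name, prof in renyi.items()},
            index=[("inf" if np.isinf(a) else a) for a in alpha.DEFAULT_ALPHAS],
        )
        renyi_df.index.name = "alpha"
        renyi_df.to_csv(out / "renyi_profiles.tsv", sep="\t")
        _write_json(
            {
                "paired_t": None if paired is None else {
                    "t": paired.statistic, "df": paired.df,
                    "p": paired.p_value, "n": paired.n,
                },
                "mean_richness": {
                    p: float(rich.loc[rich["plant"] == p, "richness"].mean())
                    for p in plants
                },
            },
            out / "alpha_summary.json",
        )
        results.update(richness=rich, paired_t=paired, renyi=renyi)

        # ------------------------------------------------ constrained ordination
        stage = "cca"
        env = ops.set_index(
            ops["plant"].astype(str) + "_M" + ops["month"].astype(int).map("{:02d}".format)
        )[reference.CCA_VARIABLES]
        env = env.loc[combined.index]
        cca_res = ordination.cca(sqrt_combined, env)
        cca_perm = ordination.cca_permutation_test(
            sqrt_combined, env, n_perm=config.n_perm_cca,
            seed=stage_seed(config.seed, "cca"), scheme=config.cca_scheme,
        )
        cca_res.site_scores.to_csv(out / "cca_site_scores.tsv", sep="\t")
        cca_res.species_scores.to_csv(out / "cca_species_scores.tsv", sep="\t")
        cca_res.biplot_scores.to_csv(out / "cca_biplot_scores.tsv", sep="\t")
        _write_json(
            {
                "eigenvalues": [float(v) for v in cca_res.eigenvalues],
                "total_inertia": cca_res.total_inertia,
                "fraction_first_two": cca_res.fraction_first_two,
                "fraction_constrained": cca_res.fraction_constrained,
                "permutation": {
                    "statistic": cca_perm.statistic, "p": cca_perm.p_value,
                    "n_perm": cca_perm.n_permutations, "scheme": cca_perm.scheme,
                },
            },
            out / "cca_summary.json",
        )
        results.update(cca=cca_res, cca_permutation=cca_perm)

        # ------------------------------------------------ performance
        stage = "performance"
        perf: dict = {"plants": {}}
        for plant, grp in ops.groupby("plant"):
            entry = {
                "bod_removal_pct": float(np.mean(
                    performance.removal_efficiency(grp["bod_in"], grp["bod_out"]))),
                "tss_removal_pct": float(np.mean(
                    performance.removal_efficiency(grp["tss_in"], grp["tss_out"]))),
            }
            reg = performance.inout_correlation(grp["bod_in"], grp["bod_out"])
            entry["bod_in_out"] = {
                "r": reg.r, "p": reg.p_value, "slope": reg.slope,
                "intercept": reg.intercept, "r_squared": reg.r_squared,
            }
            perf["plants"][str(plant)] = entry
        if ops["plant"].nunique() == 2:
            wald = performance.interaction_wald_test(
                ops["bod_in"], ops["bod_out"], ops["plant"])
            perf["interaction_wald"] = {
                "statistic": wald.statistic, "p": wald.p_value,
            }
            results["wald"] = wald
        flow = ops.set_index(
            ops["plant"].astype(str) + "_M" + ops["month"].astype(int).map("{:02d}".format)
        )["adf"]
        sf = rich.assign(flow=rich["sample_id"].map(flow))
        fit = performance.species_flow_fit(sf["richness"], sf["flow"])
        perf["species_flow"] = {
            "c": fit.c, "z": fit.z, "r_squared": fit.r_squared,
            "z_se": fit.z_se, "n_points": fit.n_points,
            "habitat_class": performance.classify_z(fit.z),
        }
        _write_json(perf, out / "performance.json")
        results.update(performance=perf, species_flow=fit)

        # ------------------------------------------------ manifest
        stage = "manifest"
        artifacts = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {p.name: _sha256(p) for p in artifacts}
        _write_json(manifest, out / "manifest.json")
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
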