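"""Synthetic sites, specimens and dual-view shell outlines.

The generator mirrors the statistical structure the downstream analysis
assumes: sites along temperature/salinity/chl-a gradients grouped into
three study systems, specimens with shell lengths spanning 25-81 mm,
and per-specimen coefficient vectors

    c = template + sum_k g_k(covariate) d_k + u_site d_site + eps

in normalized Fourier-coefficient space, where the d_k are mutually
orthonormal deformation directions for the age (length), salinity,
temperature, food and species factors, ``u_site ~ N(0, sigma_site^2)``
is a site random intercept and the residual ``eps`` is isotropic over
the free coefficients with ``sd = sigma * exp(delta * temperature)``.
Outlines are produced by inverse EFA of the coefficients, so running
the full pipeline on generated data should recover the configured
effects, the site variance and the variance-function exponent.

Templates are two fixed 7-harmonic coefficient sets: an elongated
mussel-like lateral outline and a convex-lens ventral outline.  Shapes
and effect magnitudes are synthetic constructions — chosen for a
realistic covariance hierarchy (age > salinity > temperature > food >
species), not measured from specimens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import outline_io
from .efa import EFACoefficients, NormalizationRecord, efa_inverse
from .gamm import PC_COLUMN, RESPONSE, LongShapeTable
from .outline_io import Outline

N_HARMONICS = 7

#: Normalized 7-harmonic template coefficients (a, b, c, d per row), frozen
#: from a smooth parametric mussel-like closed curve.
LATERAL_TEMPLATE = np.array(
    [
        [1.0, 0.0, 0.0, 0.5742324527],
        [0.1636860994, 0.0033018836, -0.0177330224, 0.0699587952],
        [0.0152879295, 0.0565667315, -0.0240487118, 0.0021057561],
        [0.0245999656, -0.0093552183, 0.0020341721, 0.0106989131],
        [0.0049092088, 0.0097583662, -0.0039915517, 0.0010950222],
        [0.0033941588, -0.0020692901, 0.0010117265, 0.0020968938],
        [0.0011982777, 0.0015857804, -0.0009929460, 0.0006076155],
    ]
)

#: Normalized template for the convex-lens ventral view.  The mild
#: anterior-posterior asymmetry gives harmonic 2 a dominant element well
#: above the residual noise scale, keeping the start-point sign
#: convention stable across generated specimens.
VENTRAL_TEMPLATE = np.array(
    [
        [1.0, 0.0, 0.0, 0.3283046683],
        [0.0294840295, 0.0058968059, 0.0020049140, 0.0100245700],
        [0.0171990172, 0.0, 0.0, 0.0058476658],
        [0.0, 0.0058968059, -0.0020049140, 0.0],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ]
)

FACTORS = ("length", "salinity", "temperature", "chla", "site", "species")


class SynthError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# coefficient-space geometry


def _free_indices() -> np.ndarray:
    """Indices of the combined 56-vector free to vary after normalization.

    Per view, harmonic 1's a, b, c are pinned by the normalization
    (1, 0, 0); d1 and all higher-harmonic coefficients are free.
    """
    per_view = [3] + list(range(4, 4 * N_HARMONICS))
    return np.array(per_view + [28 + i for i in per_view])


FREE = _free_indices()


def template_vector() -> np.ndarray:
    """Combined (lateral | ventral) template coefficient vector."""
    return np.concatenate([LATERAL_TEMPLATE.ravel(), VENTRAL_TEMPLATE.ravel()])


def _high_harmonic_free_mask(min_harmonic: int = 5) -> np.ndarray:
    """Mask over FREE positions that belong to harmonics >= min_harmonic."""
    mask = np.zeros(56, dtype=bool)
    for view in range(2):
        base = 28 * view
        mask[base + 4 * (min_harmonic - 1) : base + 28] = True
    return mask[FREE]


def default_directions(seed: int = 20180212) -> dict[str, np.ndarray]:
    """Mutually orthonormal deformation directions over the free coords.

    The species direction is confined to harmonics >= 5 (subtle,
    high-order shape features); the remaining factor directions are an
    orthonormalised deterministic Gaussian draw with the species
    component projected out.
    """
    rng = np.random.default_rng(seed)
    dim = len(FREE)
    high = _high_harmonic_free_mask()
    species = np.zeros(dim)
    species[high] = rng.normal(size=int(high.sum()))
    species /= np.linalg.norm(species)
    basis = [species]
    for _ in FACTORS[:-1]:
        v = rng.normal(size=dim)
        for b in basis:
            v -= (v @ b) * b
        basis.append(v / np.linalg.norm(v))
    order = list(FACTORS[:-1]) + ["species"]
    vecs = basis[1:] + [species]
    return dict(zip(order, vecs))


def _logistic(x, midpoint: float, width: float):
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - midpoint) / width))


@dataclass
class GeneratorConfig:
    """Knobs of the outline generator.

    Effect magnitudes are expressed in normalized-coefficient units and
    set a covariance hierarchy resembling the field situation: shell
    length (age) strongest, then salinity, temperature, food; the
    species offset is small and confined to high harmonics.  ``g`` for
    salinity is logistic (saturating at high salinity); the other
    covariate effects are linear.
    """

    length_slope: float = 0.0018  # per mm
    salinity_amplitude: float = 0.065  # logistic range, coeff units
    salinity_midpoint: float = 20.0  # psu
    salinity_width: float = 5.0  # psu
    temperature_slope: float = 0.0032  # per degC
    chla_slope: float = 0.0080  # per mg m^-3
    species_offset: float = 0.016  # between-species distance
    sigma_site: float = 0.008
    sigma: float = 0.004
    delta: float = -0.1  # residual sd = sigma * exp(delta * temperature)
    seed: int = 0
    directions: dict[str, np.ndarray] = field(default_factory=default_directions)
    length_range: tuple[float, float] = (25.0, 81.0)

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.sigma_site < 0:
            raise SynthError("sigma and sigma_site must be >= 0")
        dim = len(FREE)
        for k, v in self.directions.items():
            if np.asarray(v).shape != (dim,):
                raise SynthError(
                    f"direction {k!r} has shape {np.asarray(v).shape}, expected ({dim},)"
                )
        G = np.vstack(list(self.directions.values()))
        if not np.allclose(G @ G.T, np.eye(len(G)), atol=1e-8):
            raise SynthError("deformation directions must be orthonormal")

    def null(self) -> "GeneratorConfig":
        """Copy with every effect and noise magnitude set to zero."""
        return replace(
            self,
            length_slope=0.0,
            salinity_amplitude=0.0,
            temperature_slope=0.0,
            chla_slope=0.0,
            species_offset=0.0,
            sigma_site=0.0,
            sigma=0.0,
        )


# ---------------------------------------------------------------------------
# environment and specimens

DEFAULT_RANGES = {
    "temperature": (0.0, 18.0),  # degC, warm temperate to polar
    "salinity": (6.0, 35.0),  # psu, inner-Baltic brackish to fully marine
    "chla": (0.5, 5.0),  # mg m^-3
}


def generate_environment(
    n_sites: int = 15,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    correlation: float = 0.0,
) -> pd.DataFrame:
    """Synthetic site table: id, system, temperature, salinity, chl-a.

    Sites are split into the three study systems (large/medium/small
    scale, 10:4:1 proportions).  ``correlation`` induces the given
    correlation between temperature and salinity via a Gaussian copula,
    to exercise the collinearity-screening path.
    """
    if n_sites < 2:
        raise SynthError("n_sites must be >= 2")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    for k, (lo, hi) in ranges.items():
        if lo > hi:
            raise SynthError(f"invalid range for {k}: min {lo} > max {hi}")
    if not -1.0 <= correlation <= 1.0:
        raise SynthError("correlation must be in [-1, 1]")
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        np.zeros(2),
        [[1.0, correlation], [correlation, 1.0]],
        size=n_sites,
        method="cholesky",
    )
    u_t, u_s = sps.norm.cdf(z[:, 0]), sps.norm.cdf(z[:, 1])
    u_c = rng.uniform(size=n_sites)
    cols = {}
    for name, u in (("temperature", u_t), ("salinity", u_s), ("chla", u_c)):
        lo, hi = ranges[name]
        cols[name] = lo + (hi - lo) * u
    n_large = max(int(round(n_sites * 10 / 15)), 1)
    n_medium = max(int(round(n_sites * 4 / 15)), 1)
    n_small = n_sites - n_large - n_medium
    if n_small <= 0:
        n_large = max(n_large + n_small - 1, 1)
        n_small = n_sites - n_large - n_medium
    system = ["large"] * n_large + ["medium"] * n_medium + ["small"] * n_small
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n_sites)],
            "system": system[:n_sites],
            "temperature": cols["temperature"],
            "salinity": cols["salinity"],
            "chla": cols["chla"],
        }
    )


@dataclass
class SynthDataset:
    """A generated dataset: environment, specimen table and outlines."""

    env: pd.DataFrame = field(repr=False)
    specimens: pd.DataFrame = field(repr=False)
    outlines: dict[str, dict[str, Outline]] = field(repr=False)
    coefficients: dict[str, np.ndarray] = field(repr=False)
    config: GeneratorConfig | None = field(repr=False, default=None)


def _effect_sum(
    config: GeneratorConfig,
    temperature: float,
    salinity: float,
    chla: float,
    length: float,
) -> np.ndarray:
    """Deterministic part of the free-coefficient displacement."""
    d = config.directions
    # centre each g_k mid-range so the template stays near the centroid
    g_len = config.length_slope * (length - np.mean(config.length_range))
    g_sal = config.salinity_amplitude * (
        float(_logistic(salinity, config.salinity_midpoint, config.salinity_width))
        - 0.5
    )
    g_tem = config.temperature_slope * (temperature - 9.0)
    g_chl = config.chla_slope * (chla - 2.75)
    return (
        g_len * d["length"]
        + g_sal * d["salinity"]
        + g_tem * d["temperature"]
        + g_chl * d["chla"]
    )


def _to_outlines(vec: np.ndarray, specimen_id: str, n_points: int) -> dict[str, Outline]:
    out = {}
    for view, sl in (("lateral", slice(0, 28)), ("ventral", slice(28, 56))):
        coeffs = EFACoefficients(
            view,
            vec[sl].reshape(N_HARMONICS, 4),
            normalization=NormalizationRecord(normalized=True),
        )
        out[view] = efa_inverse(coeffs, n_points, specimen_id=specimen_id)
    return out


def generate_dataset(
    env: pd.DataFrame,
    n_per_site: int = 20,
    config: GeneratorConfig | None = None,
    n_points: int = 300,
    species_labels: pd.Series | None = None,
) -> SynthDataset:
    """Specimens and dual-view outlines for every site in ``env``.

    Specimen coefficient vectors follow the additive factor model in
    the module docstring; outlines are the inverse EFA of those
    vectors.  Self-intersecting outlines (possible under extreme effect
    magnitudes) are counted and reported in a warning.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    template = template_vector()
    specimens = []
    outlines: dict[str, dict[str, Outline]] = {}
    coeff_map: dict[str, np.ndarray] = {}
    n_bad = 0
    from .morphospace import _self_intersects

    for _, site in env.iterrows():
        u_site = rng.normal(0.0, config.sigma_site) if config.sigma_site else 0.0
        for k in range(n_per_site):
            sid = f"{site.site_id}_{k + 1:03d}"
            length = rng.uniform(*config.length_range)
            sd_eps = config.sigma * np.exp(config.delta * site.temperature)
            eps = rng.normal(0.0, sd_eps, size=len(FREE)) if config.sigma else 0.0
            disp = (
                _effect_sum(config, site.temperature, site.salinity, site.chla, length)
                + u_site * config.directions["site"]
                + eps
            )
            if species_labels is not None:
                sp = species_labels.get(site.site_id, "unknown")
                sign = {"edulis": 0.5, "trossulus": -0.5}.get(sp, 0.0)
                disp = disp + sign * config.species_offset * config.directions["species"]
            else:
                sp = "unknown"
            vec = template.copy()
            vec[FREE] += disp
            coeff_map[sid] = vec
            outlines[sid] = _to_outlines(vec, sid, n_points)
            if any(_self_intersects(o) for o in outlines[sid].values()):
                n_bad += 1
            specimens.append(
                {
                    "specimen_id": sid,
                    "site_id": site.site_id,
                    "system": site.system,
                    "length": length,
                    "species": sp,
                }
            )
    if n_bad:
        warnings.warn(
            f"{n_bad} generated specimens have self-intersecting outlines "
            "(effect magnitudes may be too large)",
            stacklevel=2,
        )
    return SynthDataset(
        env=env.reset_index(drop=True),
        specimens=pd.DataFrame(specimens),
        outlines=outlines,
        coefficients=coeff_map,
        config=config,
    )


def generate_reference_species(
    config: GeneratorConfig | None = None,
    n_per_species: int = 60,
    seed: int = 0,
) -> SynthDataset:
    """Two labelled reference populations (edulis-like vs trossulus-like).

    Each species occupies two sites drawn from the default environment
    ranges; the species offset acts only on harmonics >= 5 via the
    species deformation direction, so the groups overlap in PC1-PC2 but
    separate along later PCs.
    """
    if n_per_species < 3:
        raise SynthError("n_per_species must be >= 3 for leave-one-out CV")
    config = replace(config or GeneratorConfig(), seed=seed)
    env = generate_environment(4, seed=seed + 1)
    per_site = int(np.ceil(2 * n_per_species / len(env)))
    ds = generate_dataset(env, per_site, config)
    # randomized-block species assignment: within each site, alternate
    # labels down the length ordering so site, environment and age are
    # balanced between species and the offset is the only group signal
    spec = ds.specimens.copy()
    spec["species"] = ""
    for _, block in spec.groupby("site_id", sort=False):
        order = block.sort_values("length").index
        spec.loc[order[0::2], "species"] = "edulis"
        spec.loc[order[1::2], "species"] = "trossulus"
    keep = spec.groupby("species", sort=False).head(n_per_species)
    spec = keep.reset_index(drop=True)

    d_species = config.directions["species"]
    for _, row in spec.iterrows():
        sign = 0.5 if row.species == "edulis" else -0.5
        vec = ds.coefficients[row.specimen_id].copy()
        vec[FREE] += sign * config.species_offset * d_species
        ds.coefficients[row.specimen_id] = vec
        ds.outlines[row.specimen_id] = _to_outlines(vec, row.specimen_id, 300)
    return SynthDataset(
        env=env,
        specimens=spec,
        outlines={s: ds.outlines[s] for s in spec.specimen_id},
        coefficients={s: ds.coefficients[s] for s in spec.specimen_id},
        config=config,
    )


# ---------------------------------------------------------------------------
# response-scale simulation (for the mixed-model machinery)


def simulate_long_table(
    n_specimens: int = 80,
    k_pcs: int = 5,
    env: pd.DataFrame | None = None,
    length_slopes=None,
    temperature_slopes=None,
    salinity_slopes=None,
    chla_slopes=None,
    sigma_site: float = 0.3,
    sigma: float = 1.0,
    delta: float | np.ndarray = 0.0,
    variance_covariate: str = "temperature",
    seed: int = 0,
) -> LongShapeTable:
    """Simulate the stacked response directly on the score scale.

    Builds a :class:`~musselshape.gamm.LongShapeTable` whose response
    follows the additive mixed model exactly: per-PC linear covariate
    effects (slopes given as length-``k_pcs`` arrays or ``{"PC2": b}``
    dicts), a site random intercept shared across PCs, and residual
    ``sd = sigma * exp(delta_j * (v - mean(v)))``.  Covariate effects
    are centred, so all PC intercepts are zero.
    """
    rng = np.random.default_rng(seed)
    if env is None:
        env = generate_environment(15, seed=seed + 1)

    def expand(x) -> np.ndarray:
        out = np.zeros(k_pcs)
        if x is None:
            return out
        if isinstance(x, dict):
            for key, val in x.items():
                out[int(key.removeprefix("PC")) - 1] = val
            return out
        return np.asarray(x, dtype=float)

    slopes = {
        "length": expand(length_slopes),
        "temperature": expand(temperature_slopes),
        "salinity": expand(salinity_slopes),
        "chla": expand(chla_slopes),
    }
    delta = np.full(k_pcs, float(delta)) if np.isscalar(delta) else np.asarray(delta)

    site_rows = env.iloc[rng.integers(0, len(env), size=n_specimens)].reset_index(
        drop=True
    )
    length = rng.uniform(25.0, 81.0, size=n_specimens)
    u = dict(zip(env.site_id, rng.normal(0.0, sigma_site, size=len(env))))

    cov = pd.DataFrame(
        {
            "specimen_id": [f"sp{i + 1:04d}" for i in range(n_specimens)],
            "site_id": site_rows.site_id.to_numpy(),
            "temperature": site_rows.temperature.to_numpy(),
            "salinity": site_rows.salinity.to_numpy(),
            "chla": site_rows.chla.to_numpy(),
            "length": length,
        }
    )
    v = cov[variance_covariate].to_numpy()
    vc = v - v.mean()
    rows = []
    for j in range(k_pcs):
        mu = np.zeros(n_specimens)
        for name, s in slopes.items():
            x = cov[name].to_numpy()
            mu = mu + s[j] * (x - x.mean())
        mu = mu + cov.site_id.map(u).to_numpy()
        eps = rng.normal(0.0, sigma * np.exp(delta[j] * vc))
        block = cov.copy()
        block[PC_COLUMN] = f"PC{j + 1}"
        block[RESPONSE] = mu + eps
        rows.append(block)
    return LongShapeTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# fixture bundles


def write_fixture_bundle(dataset: SynthDataset, directory: str | Path) -> dict:
    """Write a dataset to plain-text files and return the manifest.

    Per specimen: one CSV outline file per view; additionally one TPS
    file per view holding every specimen (same coordinates, other
    dialect).  Plus specimen metadata and site environment CSVs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"csv_outlines": [], "tps_outlines": []}
    try:
        for view in outline_io.VIEWS:
            batch = []
            for sid in dataset.specimens.specimen_id:
                o = dataset.outlines[sid][view]
                p = directory / f"{sid}_{view}.csv"
                outline_io.write_outline_csv(o, p)
                manifest["csv_outlines"].append(p.name)
                batch.append(o)
            tps_path = directory / f"outlines_{view}.tps"
            outline_io.write_outline_tps(batch, tps_path)
            manifest["tps_outlines"].append(tps_path.name)
        meta = directory / "specimens.csv"
        dataset.specimens.rename(columns={"length": "length_mm"}).to_csv(
            meta, index=False
        )
        manifest["specimens"] = meta.name
        envp = directory / "environment.csv"
        dataset.env.rename(
            columns={
                "temperature": "temperature_c",
                "salinity": "salinity_psu",
                "chla": "chla_mg_m3",
            }
        ).to_csv(envp, index=False)
        manifest["environment"] = envp.name
    except OSError as exc:
        raise OSError(
            f"failed writing fixture bundle under {directory}: {exc}"
        ) from exc
    return manifest


def read_fixture_bundle(directory: str | Path) -> SynthDataset:
    """Read back a bundle written by :func:`write_fixture_bundle`."""
    directory = Path(directory)
    spec = pd.read_csv(directory / "specimens.csv").rename(
        columns={"length_mm": "length"}
    )
    env = pd.read_csv(directory / "environment.csv").rename(
        columns={
            "temperature_c": "temperature",
            "salinity_psu": "salinity",
            "chla_mg_m3": "chla",
        }
    )
    outlines: dict[str, dict[str, Outline]] = {}
    for sid in spec.specimen_id:
        outlines[sid] = {}
        for view in outline_io.VIEWS:
            path = directory / f"{sid}_{view}.csv"
            outlines[sid][view] = outline_io.read_outlines(path, "csv")[0]
    return SynthDataset(
        env=env, specimens=spec, outlines=outlines, coefficients={}, config=None
    )
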