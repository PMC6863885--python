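"""Synthetic mining landscapes, sample designs and SNP genotypes.

The generator emulates the study system every downstream stage is built
for: montane-savanna (canga) plateaus surrounded by forest, an open-pit
mine that expands over the years by consuming canga from a fixed edge
(habitat loss without fragmentation), spatially smooth climate fields,
spatially clustered individuals, and genotypes whose pairwise relatedness
decays with the circuit-theory commute distance on a known ("true")
resistance surface.  Quality-control violations are planted with exact
bookkeeping so filter pipelines can be tested against ground truth.

Genotype model
--------------
Ancestral allele frequencies p_i ~ Uniform(0.05, 0.95).  Cluster
frequencies follow the Balding-Nichols model,
Beta(p(1-F)/F, (1-p)(1-F)/F), at a target differentiation F.  Individual
ancestry proportions q_jk come from a spatial softmax gradient anchored at
K landscape locations.  Genotypes are Binomial(2, pi_ij) with
logit(pi_ij) = logit(sum_k q_jk p_ik) + eta_ij, where each locus's eta is
multivariate normal with covariance sigma^2 exp(-D / phi) and D the
effective-resistance distance on the true surface — the isolation-by-
resistance signal inference should recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.ndimage import label as ndimage_label
from scipy.special import expit, logit

from .genotypes import MISSING, GenotypeTable, write_vcf
from .raster import RasterGrid, write_ascii_grid
from .resistance import categorical_surface, commute_distance

__all__ = [
    "CLASS_CODES", "LandscapeTruth", "SampleSet", "make_landscape",
    "sample_locations", "simulate_genotypes", "write_fixtures",
    "ARTIFACT_RULES",
]

#: Land-cover class codes: the three classes partition every grid.
CLASS_CODES = {"canga": 0, "forest": 1, "mine": 2}

#: Planted QC-violation categories understood by :func:`simulate_genotypes`.
ARTIFACT_RULES = ("missing", "low_qual", "bad_depth", "rare", "all_het",
                  "hwe", "ld_dup", "fst_outlier")

_CLIMATE_NAMES = ["bio06", "bio16", "bio19", "bio04", "elevation", "roughness"]


@dataclass
class LandscapeTruth:
    """Everything the simulator knew, stored verbatim for recovery tests."""

    class_maps: dict            # year -> RasterGrid of class codes
    climate_fields: dict        # name -> RasterGrid (continuous)
    true_resistance: dict       # class name -> resistance value
    cluster_params: dict        # K, fst, anchor points, softmax scale
    gp_params: dict             # sigma2, phi_frac (of max commute distance)
    seed: int

    @property
    def years(self) -> list[int]:
        return sorted(self.class_maps)

    @property
    def latest_map(self) -> RasterGrid:
        return self.class_maps[self.years[-1]]

    def mine_counts(self) -> dict:
        return {y: int((g.data == CLASS_CODES["mine"]).sum())
                for y, g in self.class_maps.items()}


@dataclass
class SampleSet:
    """Sampled individuals: ids, projected coordinates, truth labels."""

    ids: list
    coords: np.ndarray
    region: str = "serra_a"
    true_cluster: np.ndarray | None = None
    true_ancestry: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids,
                           "x": self.coords[:, 0], "y": self.coords[:, 1],
                           "region": self.region})
        if self.true_cluster is not None:
            df["true_cluster"] = self.true_cluster
        return df


def _smooth_field(shape, rng, sigma) -> np.ndarray:
    f = gaussian_filter(rng.normal(size=shape), sigma=sigma, mode="reflect")
    f = (f - f.mean()) / f.std()
    return f


def make_landscape(grid_size: int = 60,
                   years: tuple = (1979, 2011, 2014, 2016),
                   mine_growth_schedule: dict | None = None,
                   n_climate_fields: int = 4,
                   seed: int = 0,
                   cell_size: float = 1.0,
                   true_resistance: dict | None = None,
                   cluster_params: dict | None = None,
                   gp_params: dict | None = None) -> LandscapeTruth:
    """Generate a multi-year mining landscape with known parameters.

    The canga plateau is a crescent opening east, with forest elsewhere.
    The mine grows from a fixed cell on the plateau's western edge by
    boundary accretion as an elongated pit along the crescent spine, so
    later maps lose canga without fragmenting it.  ``mine_growth_schedule`` maps each year to a
    target mine cell count; the earliest (pre-mining) year must be 0 and
    counts must be non-decreasing.
    """
    years = tuple(sorted(years))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if mine_growth_schedule is None:
        area = grid_size * grid_size
        mine_growth_schedule = {y: 0 for y in years[:1]}
        for i, y in enumerate(years[1:], start=1):
            mine_growth_schedule[y] = int(0.04 * area * i)
    sched = {int(y): int(mine_growth_schedule.get(y, 0)) for y in years}
    if sched[years[0]] != 0:
        raise ValueError(f"pre-mining year {years[0]} must have 0 mine cells")
    counts = [sched[y] for y in years]
    if any(b < a for a, b in zip(counts, counts[1:])):
        raise ValueError("mine cell counts must be non-decreasing over years")

    # canga plateau: a crescent with a noisy boundary.  The forest bay in
    # the crescent's opening gives some sample pairs a short path through
    # forest (making forest resistance identifiable), while travel along
    # the crescent stays in canga.
    nr = nc = grid_size
    f = _smooth_field((nr, nc), rng, sigma=grid_size / 8)
    yy, xx = np.mgrid[0:nr, 0:nc]
    cy, cx = (nr - 1) / 2, (nc - 1) / 2
    rad = np.sqrt(((yy - cy) / (0.48 * nr)) ** 2 + ((xx - cx) / (0.48 * nc)) ** 2)
    theta = np.arctan2(yy - cy, xx - cx)  # 0 points east
    bay = (np.abs(theta) < np.deg2rad(55)) & (rad > 0.33)
    canga = (rad + 0.08 * f < 1.0) & ~bay
    # keep only the largest connected canga patch (boundary noise can shed
    # islets; the pre-mining plateau must be one fragment)
    lab, ncomp = ndimage_label(canga)
    if ncomp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        canga = lab == (int(np.argmax(sizes)) + 1)
    base = np.where(canga, CLASS_CODES["canga"], CLASS_CODES["forest"])
    n_canga = int(canga.sum())
    for y in years:
        if sched[y] > n_canga:
            raise ValueError(
                f"mine target {sched[y]} for year {y} exceeds canga area {n_canga}")

    # fixed start cell: the median row of the westernmost canga column; the
    # pit then grows eastward along the crescent spine as an elongated
    # finger, the shape open-pit mines take along an ore body
    cols = np.where(canga.any(axis=0))[0]
    c0 = int(cols.min())
    rows_at_c0 = np.where(canga[:, c0])[0]
    r0 = int(np.median(rows_at_c0))
    order = _accretion_order(canga, (r0, c0))
    max_target = counts[-1]
    eaten = order[:max_target]

    class_maps = {}
    for y in years:
        m = base.copy()
        k = sched[y]
        if k:
            idx = eaten[:k]
            m[idx[:, 0], idx[:, 1]] = CLASS_CODES["mine"]
        class_maps[y] = RasterGrid(data=m.astype(float), cell_size=cell_size,
                                   name="landcover", year=y)

    climate_fields = {}
    for i in range(n_climate_fields):
        name = _CLIMATE_NAMES[i] if i < len(_CLIMATE_NAMES) else f"clim_{i}"
        climate_fields[name] = RasterGrid(
            data=_smooth_field((nr, nc), rng, sigma=grid_size / (5 + 2 * i)),
            cell_size=cell_size, name=name)

    return LandscapeTruth(
        class_maps=class_maps,
        climate_fields=climate_fields,
        true_resistance=dict(true_resistance
                             or {"canga": 1.0, "forest": 3.0, "mine": 8.0}),
        cluster_params=dict(cluster_params
                            or {"K": 2, "fst": 0.10, "softmax_scale": 0.03}),
        gp_params=dict(gp_params or {"sigma2": 0.35, "kernel": "commute",
                                     "phi_frac": 1.5}),
        seed=seed,
    )


def _accretion_order(canga: np.ndarray, start: tuple[int, int],
                     aniso: float = 8.0) -> np.ndarray:
    """Deterministic boundary-accretion order of canga cells from a start cell.

    At each step the frontier cell with the smallest anisotropic distance to
    the start is consumed (rows weighted ``aniso`` times more than columns,
    ties by row then column), so the pit grows as an elongated contiguous
    finger — habitat loss without fragmentation.
    """
    import heapq
    nr, nc = canga.shape
    remaining = canga.copy()
    heap = [(0.0, start[0], start[1])]
    seen = {start}
    order = []
    deferred: list = []
    while heap or deferred:
        if not heap:
            break
        _, r, c = heapq.heappop(heap)
        if not remaining[r, c]:
            continue
        # never split the remaining habitat: defer articulation cells
        remaining[r, c] = False
        _, ncomp = ndimage_label(remaining)
        if ncomp > 1 and remaining.any():
            remaining[r, c] = True
            deferred.append((aniso * (r - start[0]) ** 2
                             + 0.2 * (c - start[1]) ** 2, r, c))
            if not heap:
                break
            continue
        order.append((r, c))
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and canga[r2, c2] and (r2, c2) not in seen:
                seen.add((r2, c2))
                d = aniso * (r2 - start[0]) ** 2 + 0.2 * (c2 - start[1]) ** 2
                heapq.heappush(heap, (d, r2, c2))
        if deferred:
            for item in deferred:
                heapq.heappush(heap, item)
            deferred = []
    return np.array(order)


def sample_locations(truth: LandscapeTruth, n: int, min_dist: float,
                     seed: int = 0, region: str = "serra_a",
                     max_attempts: int = 200) -> SampleSet:
    """Sample locations on canga cells of the most recent map.

    Points are cell centers chosen by rejection sampling so that every
    pairwise distance is >= ``min_dist`` (mirroring the field rule of
    spacing samples to avoid collecting close kin).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if min_dist < 0:
        raise ValueError("min_dist must be >= 0")
    grid = truth.latest_map
    canga_cells = np.argwhere(grid.data == CLASS_CODES["canga"])
    if n > len(canga_cells):
        raise ValueError(
            f"cannot place {n} samples on {len(canga_cells)} canga cells")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    centers = np.array([grid.center_of(r, c) for r, c in canga_cells])
    for _ in range(max_attempts):
        perm = rng.permutation(len(centers))
        chosen: list[int] = []
        for i in perm:
            p = centers[i]
            if all(np.hypot(*(p - centers[j])) >= min_dist for j in chosen):
                chosen.append(i)
                if len(chosen) == n:
                    break
        if len(chosen) == n:
            coords = centers[chosen]
            ids = [f"{region}_{i:03d}" for i in range(n)]
            return SampleSet(ids=ids, coords=coords, region=region)
    raise ValueError(
        f"could not place {n} samples at min_dist={min_dist} after "
        f"{max_attempts} attempts")


def _ancestry_gradient(coords: np.ndarray, K: int, extent: float,
                       softmax_scale: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Ancestry proportions from a spatial softmax over K anchor points."""
    if K == 1:
        return np.ones((len(coords), 1)), np.zeros((1, 2))
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    ang = 2 * np.pi * np.arange(K) / K + np.pi / 4
    center = (lo + hi) / 2
    radius = (hi - lo) / 2
    anchors = center + np.column_stack([np.cos(ang), np.sin(ang)]) * radius
    d = np.sqrt(((coords[:, None, :] - anchors[None, :, :]) ** 2).sum(-1))
    tau = softmax_scale * extent
    a = -d / tau
    a -= a.max(axis=1, keepdims=True)
    q = np.exp(a)
    return q / q.sum(axis=1, keepdims=True), anchors


def simulate_genotypes(truth: LandscapeTruth, samples: SampleSet,
                       n_loci: int = 1000, artifact_spec: dict | None = None,
                       seed: int = 0, year: int | None = None,
                       missing_rate: float = 0.02,
                       max_repair: int = 50):
    """Simulate SNP genotypes with known structure and IBR signal.

    Returns ``(GenotypeTable, truth_record)`` where ``truth_record`` maps
    each planted artifact rule to the exact locus indices affected, and
    carries the simulation internals (ancestry, commute distances, eta
    covariance parameters) for recovery tests.

    ``artifact_spec`` maps rule names from :data:`ARTIFACT_RULES` to planted
    locus counts; planted sets are disjoint.  Clean loci are repaired
    (redrawn) if they accidentally violate the frequency/heterozygosity
    rules, so planted counts are exact; accidental Hardy-Weinberg
    violations are only repaired for unstructured simulations (structured
    data violates a pooled HWE test by construction — the Wahlund effect).
    """
    spec = {k: int(v) for k, v in (artifact_spec or {}).items()}
    unknown = set(spec) - set(ARTIFACT_RULES)
    if unknown:
        raise ValueError(f"unknown artifact rules: {sorted(unknown)}")
    n_planted = sum(spec.values())
    if n_planted > n_loci:
        raise ValueError(f"{n_planted} planted artifacts exceed {n_loci} loci")
    if n_loci < 100:
        raise ValueError("n_loci must be >= 100")
    K = int(truth.cluster_params.get("K", 1))
    fst = float(truth.cluster_params.get("fst", 0.1))
    sigma2 = float(truth.gp_params.get("sigma2", 0.0))
    if sigma2 > 0 and K == 0:
        raise ValueError("sigma2 > 0 requires K >= 1")
    n = samples.n
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, seed, 2)))

    # --- spatial pieces -------------------------------------------------
    year = year if year is not None else truth.years[-1]
    class_map = truth.class_maps[year]
    res_values = {CLASS_CODES[k]: v for k, v in truth.true_resistance.items()}
    surface = categorical_surface(class_map, res_values)
    D = commute_distance(surface, samples.coords).matrix
    kernel = truth.gp_params.get("kernel", "commute")
    phi = float(truth.gp_params.get("phi_frac", 1.5)) * float(D.max() or 1.0)
    if sigma2 > 0:
        if kernel == "exponential":
            cov = sigma2 * np.exp(-D / phi)
        elif kernel == "commute":
            # commute-time kernel: effective resistance is of negative type,
            # so -1/2 H D H is PSD; expected relatedness is then LINEAR in
            # distance, the relationship the downstream models fit
            H = np.eye(n) - 1.0 / n
            Kmat = -0.5 * H @ D @ H
            Kmat = Kmat / max(np.mean(np.diag(Kmat)), 1e-300)
            cov = sigma2 * Kmat
        else:
            raise ValueError(f"unknown gp kernel {kernel!r}")
        chol = np.linalg.cholesky(cov + 1e-8 * np.eye(n))
    else:
        chol = None

    xmin, ymin = samples.coords.min(axis=0)
    xmax, ymax = samples.coords.max(axis=0)
    extent = max(xmax - xmin, ymax - ymin)
    q, anchors = _ancestry_gradient(
        samples.coords, K, extent,
        float(truth.cluster_params.get("softmax_scale", 0.03)), rng)
    samples.true_ancestry = q
    samples.true_cluster = q.argmax(axis=1)

    # --- clean genotype draw -------------------------------------------
    def draw_locus(r):
        p = r.uniform(0.05, 0.95)
        if K > 1 and fst > 0:
            a = p * (1 - fst) / fst
            b = (1 - p) * (1 - fst) / fst
            pk = r.beta(a, b, size=K)
        else:
            pk = np.full(K, p)
        pi = q @ pk
        if chol is not None:
            eta = chol @ r.normal(size=n)
            pi = expit(logit(np.clip(pi, 1e-9, 1 - 1e-9)) + eta)
        x = r.binomial(2, pi).astype(np.int8)
        miss = r.random(n) < missing_rate
        x[miss] = MISSING
        return x, pk

    dosages = np.empty((n, n_loci), dtype=np.int8)
    cluster_freqs = np.empty((K, n_loci))
    for i in range(n_loci):
        dosages[:, i], cluster_freqs[:, i] = draw_locus(rng)

    qual = np.clip(rng.normal(90, 15, n_loci), 55, None)
    mean_depth = np.clip(rng.lognormal(np.log(90), 0.35, n_loci), 35, 230)

    # --- plant artifacts (disjoint sets) --------------------------------
    avail = rng.permutation(n_loci)
    planted: dict[str, np.ndarray] = {}
    # LD duplicates take the largest locus indices: pruning drops the larger
    # index of a tied pair, so the removed locus is exactly the planted copy.
    ld_k = spec.get("ld_dup", 0)
    if ld_k:
        planted["ld_dup"] = np.arange(n_loci - ld_k, n_loci)
        avail = avail[~np.isin(avail, planted["ld_dup"])]
    else:
        planted["ld_dup"] = np.array([], dtype=int)
    pos = 0
    for rule in ARTIFACT_RULES:
        if rule == "ld_dup":
            continue
        k = spec.get(rule, 0)
        planted[rule] = np.sort(avail[pos:pos + k])
        pos += k
    clean = np.sort(avail[pos:])

    for i in planted["missing"]:
        m = int(np.ceil(0.31 * n)) + int(rng.integers(0, max(n // 10, 1)))
        idx = rng.choice(n, size=min(m, n), replace=False)
        dosages[idx, i] = MISSING
    qual[planted["low_qual"]] = rng.uniform(20, 50, len(planted["low_qual"]))
    for j, i in enumerate(planted["bad_depth"]):
        mean_depth[i] = rng.uniform(5, 29) if j % 2 == 0 else rng.uniform(241, 400)
    for i in planted["rare"]:
        col = np.zeros(n, dtype=np.int8)
        if 1.0 / (2 * n) < 0.03:
            col[rng.integers(0, n)] = 1
        dosages[:, i] = col
    for i in planted["all_het"]:
        dosages[:, i] = 1
    for i in planted["hwe"]:
        col = np.where(np.arange(n) % 2 == 0, 0, 2).astype(np.int8)
        dosages[:, i] = rng.permutation(col)
    dup_source = {}
    for i in planted["ld_dup"]:
        src = int(rng.choice(clean))
        dup_source[int(i)] = src
        dosages[:, i] = dosages[:, src]
    for i in planted["fst_outlier"]:
        lo = rng.uniform(0.10, 0.25)
        pk = np.array([lo if k % 2 == 0 else lo + 0.5 for k in range(max(K, 1))])
        pi = (q @ pk) if K > 1 else np.full(n, pk[0])
        dosages[:, i] = rng.binomial(2, pi).astype(np.int8)

    # --- repair accidental violations among clean loci ------------------
    unstructured = (K == 1 and sigma2 == 0)
    from .variant_qc import hwe_exact_test

    def violates(i) -> bool:
        col = dosages[:, i]
        ok = col != MISSING
        nn = int(ok.sum())
        if nn == 0:
            return True
        p = col[ok].sum() / (2.0 * nn)
        maf = min(p, 1 - p)
        if maf < 0.03:
            return True
        if np.all(col[ok] == 1):
            return True
        if (~ok).mean() > 0.30:
            return True
        if unstructured:
            counts = [(col == g).sum() for g in (0, 1, 2)]
            if hwe_exact_test(*counts) < 1e-4:
                return True
        return False

    for i in clean:
        tries = 0
        while violates(i) and tries < max_repair:
            dosages[:, i], cluster_freqs[:, i] = draw_locus(rng)
            tries += 1
    for i in planted["ld_dup"]:
        dosages[:, i] = dosages[:, dup_source[int(i)]]

    loci = pd.DataFrame({
        "id": [f"tag_{i:05d}" for i in range(n_loci)],
        "pos": np.arange(1, n_loci + 1),
        "qual": qual,
        "mean_depth": mean_depth,
    })
    geno = GenotypeTable(dosages, loci, list(samples.ids))
    truth_record = {
        "planted": {k: v.tolist() for k, v in planted.items()},
        "dup_source": dup_source,
        "clean": clean.tolist(),
        "cluster_freqs": cluster_freqs,
        "ancestry": q,
        "anchors": anchors,
        "commute_distance": D,
        "phi": phi,
        "sigma2": sigma2,
        "K": K,
        "fst": fst,
        "year": year,
        "seed": seed,
    }
    return geno, truth_record


def write_fixtures(geno: GenotypeTable, samples: SampleSet,
                   truth: LandscapeTruth, out_dir: str | Path) -> dict:
    """Write VCF, coordinate CSV and one ASCII raster per layer/year.

    Returns (and writes) a manifest of produced files; reading the files
    back reproduces the inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"vcf": str(out / "genotypes.vcf"),
                      "coordinates": str(out / "coordinates.csv"),
                      "landcover": {}, "climate": {}}
    write_vcf(geno, manifest["vcf"])
    samples.to_frame().to_csv(manifest["coordinates"], index=False)
    for year, grid in truth.class_maps.items():
        p = out / f"landcover_{year}.asc"
        write_ascii_grid(grid, p)
        manifest["landcover"][str(year)] = str(p)
    for name, grid in truth.climate_fields.items():
        p = out / f"{name}.asc"
        write_ascii_grid(grid, p)
        manifest["climate"][name] = str(p)
    manifest["params"] = {
        "true_resistance": truth.true_resistance,
        "cluster_params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                           for k, v in truth.cluster_params.items()},
        "gp_params": truth.gp_params,
        "seed": truth.seed,
        "class_codes": CLASS_CODES,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
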