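"""Synthetic stimuli, ground-truth similarity, and simulated experiments.

Everything the analysis pipelines consume can be generated here: a
letter x font grid of glyph images, a latent pixel-based dissimilarity
structure over letters, trial tables for both behavioral tasks with the
statistical structure the pipelines assume (lognormally skewed search RTs
with per-session speed offsets; categorization RTs with per-session random
intercepts and similarity-dependent rejection slowing), and an untrained
multi-stage feature hierarchy over the glyphs.

Glyph "fonts" are parametric perturbations (scale, slant, stroke width,
positional jitter) of fixed fourteen-segment letter templates; no font
files are involved.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CategHITSpec, SearchHITSpec
from .models import ActivationSet, pool_feature_maps
from .rdm import RDM

__all__ = [
    "GlyphSet",
    "SearchParams",
    "CategParams",
    "GroundTruth",
    "render_glyphs",
    "truth_rdm_from_glyphs",
    "default_truth",
    "simulate_search",
    "simulate_categ",
    "simulate_feature_hierarchy",
    "synthetic_intuitive_table",
]

# fourteen-segment skeleton on a 1 x 2 grid (x right, y up)
_P = {
    "TL": (0.0, 2.0), "TC": (0.5, 2.0), "TR": (1.0, 2.0),
    "ML": (0.0, 1.0), "C": (0.5, 1.0), "MR": (1.0, 1.0),
    "BL": (0.0, 0.0), "BC": (0.5, 0.0), "BR": (1.0, 0.0),
}
_SEGMENTS = {
    "a": ("TL", "TR"), "b": ("TR", "MR"), "c": ("MR", "BR"), "d": ("BL", "BR"),
    "e": ("ML", "BL"), "f": ("TL", "ML"), "g1": ("ML", "C"), "g2": ("C", "MR"),
    "h": ("TL", "C"), "i": ("TC", "C"), "j": ("TR", "C"),
    "k": ("C", "BL"), "l": ("C", "BC"), "m": ("C", "BR"),
}
# segment patterns for the 26 letters (stylized, mutually distinct)
_LETTER_SEGMENTS = {
    "a": "a b c e f g1 g2", "b": "a b c d g2 i l", "c": "a d e f",
    "d": "a b c d i l", "e": "a d e f g1 g2", "f": "a e f g1",
    "g": "a c d e f g2", "h": "b c e f g1 g2", "i": "a d i l",
    "j": "b c d e", "k": "e f g1 j m", "l": "d e f",
    "m": "b c e f h j", "n": "b c e f h m", "o": "a b c d e f",
    "p": "a b e f g1 g2", "q": "a b c d e f m", "r": "a b e f g1 g2 m",
    "s": "a c d f g1 g2", "t": "a i l", "u": "b c d e f",
    "v": "e f j", "w": "b c e f k m", "x": "h j k m",
    "y": "h j l", "z": "a d j k",
}


@dataclass
class GlyphSet:
    """Complete letter x font grid of binary glyph rasters."""

    alphabet: list[str]
    fonts: list[str]
    images: np.ndarray  # (n_letters, n_fonts, size, size) in {0, 1}
    font_params: pd.DataFrame = field(default=None, repr=False)

    @property
    def image_size(self) -> int:
        return self.images.shape[-1]

    @property
    def n_images(self) -> int:
        return self.images.shape[0] * self.images.shape[1]

    def flat(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(images, letter labels, font labels) flattened over the grid."""
        L, F = len(self.alphabet), len(self.fonts)
        imgs = self.images.reshape(L * F, self.image_size, self.image_size)
        letters = np.repeat(self.alphabet, F)
        fonts = np.tile(self.fonts, L)
        return imgs, letters, fonts


def _segment_distance(px, py, a, b):
    ax, ay = a
    bx, by = b
    dx, dy = bx - ax, by - ay
    denom = dx * dx + dy * dy
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / denom, 0.0, 1.0) if denom else 0.0
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def render_glyphs(
    alphabet: str = "abcdefghijklmnopqrstuvwxyz",
    n_fonts: int = 20,
    image_size: int = 32,
    seed: int = 0,
) -> GlyphSet:
    """Render a deterministic glyph grid; fonts differ parametrically.

    Each font draws a scale, slant (horizontal shear), stroke width, and
    per-glyph positional jitter from the seeded generator and renders all
    letters of ``alphabet`` with them.
    """
    letters = list(alphabet)
    unknown = [l for l in letters if l not in _LETTER_SEGMENTS]
    if unknown:
        raise ValueError(f"no glyph template for letter(s) {unknown}")
    if n_fonts < 1:
        raise ValueError("n_fonts must be >= 1")
    if image_size < 12:
        raise ValueError("image too small to render strokes")
    rng = np.random.default_rng(seed)
    S = image_size
    yy, xx = np.mgrid[0:S, 0:S].astype(float)

    params = []
    images = np.zeros((len(letters), n_fonts, S, S))
    for f in range(n_fonts):
        scale = rng.uniform(0.62, 0.85)
        slant = rng.uniform(-0.22, 0.22)
        stroke = rng.uniform(0.045, 0.10) * S
        jitter_sd = rng.uniform(0.0, 0.015) * S
        params.append(dict(font=f"font{f:02d}", scale=scale, slant=slant,
                           stroke=stroke, jitter_sd=jitter_sd))
        for li, letter in enumerate(letters):
            jx, jy = rng.normal(0.0, jitter_sd, size=2)
            # glyph grid spans x in [0,1], y in [0,2]; center it in the image
            sx = scale * S / 2.0
            sy = scale * S / 2.0
            cx, cy = S / 2.0 + jx, S / 2.0 + jy
            ink = np.zeros((S, S), dtype=bool)
            for seg in _LETTER_SEGMENTS[letter].split():
                (p1, p2) = _SEGMENTS[seg]
                pts = []
                for name in (p1, p2):
                    gx, gy = _P[name]
                    x = cx + sx * (gx - 0.5) + slant * sy * (gy - 1.0)
                    y = cy - sy * (gy - 1.0)  # raster y grows downward
                    pts.append((x, y))
                d = _segment_distance(xx, yy, pts[0], pts[1])
                ink |= d <= stroke / 2.0
            images[li, f] = ink.astype(float)
    return GlyphSet(letters, [p["font"] for p in params], images, pd.DataFrame(params))


def truth_rdm_from_glyphs(glyphs: GlyphSet) -> RDM:
    """Latent pixel-space dissimilarity: mean over fonts of within-font
    Euclidean pixel distances, normalized to a maximum of 1."""
    L, F = len(glyphs.alphabet), len(glyphs.fonts)
    X = glyphs.images.reshape(L, F, -1)
    acc = np.zeros((L, L))
    for f in range(F):
        diff = X[:, f, None, :] - X[None, :, f, :]
        acc += np.sqrt((diff**2).sum(axis=-1))
    acc /= F
    peak = acc.max()
    if peak > 0:
        acc /= peak
    return RDM(glyphs.alphabet, acc)


@dataclass
class SearchParams:
    """Generative parameters for odd-one-out search reaction times.

    Log RTs follow baseline + per-HIT offset + slope * similarity + noise,
    so raw RTs are lognormally skewed and uniformly rescaling a HIT's RTs
    shifts only its offset.  Similarity is 1 minus the normalized latent
    dissimilarity; the positive slope makes search slower for more similar
    target-distractor pairs.  Defaults give ~600 ms baseline RTs with a
    within-HIT log-RT spread typical of speeded search.
    """

    baseline_log_rt: float = 6.35   # log ms, ~572 ms
    hit_offset_sd: float = 0.15    # between-session speed spread (log units)
    similarity_slope: float = 0.40  # log-RT increase from sim 0 to 1
    residual_sd: float = 0.20      # trial noise (log units)
    lapse_rate: float = 0.005      # far-tail attention lapses
    error_base: float = 0.01
    error_slope: float = 0.10      # error probability grows with similarity


@dataclass
class CategParams:
    """Generative parameters for categorization reaction times (ms).

    Non-match RTs follow baseline + per-HIT intercept + slope * similarity
    + noise; match trials sit at baseline.  Defaults give ~550 ms
    responses with similarity-dependent rejection slowing of up to 150 ms.
    """

    baseline_ms: float = 550.0
    hit_intercept_sd: float = 60.0
    similarity_slope_ms: float = 150.0
    residual_sd_ms: float = 120.0
    error_base: float = 0.02
    error_slope: float = 0.08
    min_rt_ms: float = 150.0


@dataclass
class GroundTruth:
    """Latent similarity structure plus generative RT parameters."""

    rdm: RDM
    search: SearchParams = field(default_factory=SearchParams)
    categ: CategParams = field(default_factory=CategParams)

    def similarity(self, a: str, b: str) -> float:
        """1 minus normalized dissimilarity of an unordered letter pair."""
        i, j = self.rdm.labels.index(a), self.rdm.labels.index(b)
        return 1.0 - float(self.rdm.values[i, j])


def default_truth(seed: int = 0, n_letters: int = 6, n_fonts: int = 6) -> GroundTruth:
    """Ground truth from a rendered glyph set at the default test scale."""
    glyphs = render_glyphs(
        "abcdefghijklmnopqrstuvwxyz"[:n_letters], n_fonts=n_fonts, seed=seed
    )
    return GroundTruth(truth_rdm_from_glyphs(glyphs))


def _sim_lookup(truth: GroundTruth) -> dict[tuple[str, str], float]:
    out = {}
    labels = truth.rdm.labels
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            out[(a, b)] = 1.0 - float(truth.rdm.values[i, j])
    return out


def simulate_search(
    truth: GroundTruth, designs: list[SearchHITSpec], seed: int
) -> pd.DataFrame:
    """Simulate a visual-search trial table from ground truth.

    Returns the standard search trial table (hit_id, letter_a, letter_b,
    target, font, correct, rt_ms), seeded and reproducible.
    """
    p = truth.search
    sim = _sim_lookup(truth)
    rng = np.random.default_rng(seed)
    rows = []
    for hit in designs:
        offset = rng.normal(0.0, p.hit_offset_sd)
        for t in hit.trials:
            a, b = sorted(t.pair)
            if (a, b) not in sim:
                raise ValueError(f"design pair {(a, b)} outside the truth alphabet")
            s = sim[(a, b)]
            lr = (p.baseline_log_rt + offset + p.similarity_slope * s
                  + rng.normal(0.0, p.residual_sd))
            if rng.random() < p.lapse_rate:
                rt = rng.uniform(4000.0, 12000.0)
            else:
                rt = float(np.exp(lr))
            p_err = min(1.0, max(0.0, p.error_base + p.error_slope * s))
            rows.append(
                dict(hit_id=hit.hit_id, letter_a=a, letter_b=b, target=t.target,
                     font=hit.font, correct=bool(rng.random() >= p_err),
                     rt_ms=rt)
            )
    return pd.DataFrame(rows)


def simulate_categ(
    truth: GroundTruth, designs: list[CategHITSpec], seed: int
) -> pd.DataFrame:
    """Simulate a categorization trial table from ground truth.

    Returns the standard categorization trial table (hit_id, block,
    target, presented, font, match, correct, rt_ms).
    """
    p = truth.categ
    sim = _sim_lookup(truth)
    rng = np.random.default_rng(seed)
    rows = []
    for hit in designs:
        intercept = rng.normal(0.0, p.hit_intercept_sd)
        for t in hit.trials:
            target = hit.blocks[t.block].target
            if t.match:
                mu = p.baseline_ms + intercept
                p_err = p.error_base
            else:
                key = (target, t.presented)
                if key not in sim:
                    raise ValueError(f"design pair {key} outside the truth alphabet")
                mu = p.baseline_ms + intercept + p.similarity_slope_ms * sim[key]
                p_err = min(1.0, max(0.0, p.error_base + p.error_slope * sim[key]))
            rt = max(p.min_rt_ms, mu + rng.normal(0.0, p.residual_sd_ms))
            rows.append(
                dict(hit_id=hit.hit_id, block=t.block, target=target,
                     presented=t.presented, font=t.font, match=t.match,
                     correct=bool(rng.random() >= p_err), rt_ms=rt)
            )
    return pd.DataFrame(rows)


def synthetic_intuitive_table(alphabet: str = "abcdefghijklmnopqrstuvwxyz") -> pd.DataFrame:
    """Synthetic stand-in for a hand-rated intuitive letter-feature table.

    The published tables of rated letter features (line orientations,
    curves, intersections, terminations, diacritics, symmetry, closed
    space) are hand judgments and are not distributed; this function
    computes the analogous counts mechanically from this package's
    segment-based glyph templates, so the intuitive-feature pipeline can
    be exercised end to end.  The glyph templates contain no curves or
    diacritics, so those columns are zero.  Terminations at the center
    node are counted as bottom terminations by convention.
    """
    rows = []
    for letter in alphabet:
        segs = _LETTER_SEGMENTS[letter].split()
        pts = [(_P[a], _P[b]) for a, b in (_SEGMENTS[s] for s in segs)]
        counts = dict.fromkeys(
            ["line_vertical", "line_horizontal", "line_slant_right",
             "line_slant_left", "curve_open_right", "curve_open_left",
             "curve_open_bottom", "curve_open_top", "intersection_2way",
             "intersection_3way", "intersection_4way", "termination_right",
             "termination_left", "termination_bottom", "termination_top",
             "diacritic", "symmetry", "closed_space"], 0)
        degree: dict[tuple, list] = {}
        for (a, b) in pts:
            dx, dy = b[0] - a[0], b[1] - a[1]
            if dx == 0:
                counts["line_vertical"] += 1
            elif dy == 0:
                counts["line_horizontal"] += 1
            elif dy / dx > 0:
                counts["line_slant_right"] += 1
            else:
                counts["line_slant_left"] += 1
            for p, q in ((a, b), (b, a)):
                degree.setdefault(p, []).append(
                    ((q[0] - p[0]), (q[1] - p[1]))
                )
        for (x, y), dirs in degree.items():
            d = len(dirs)
            if d == 1:
                if x == 1.0:
                    counts["termination_right"] += 1
                elif x == 0.0:
                    counts["termination_left"] += 1
                elif y == 2.0:
                    counts["termination_top"] += 1
                else:
                    counts["termination_bottom"] += 1
            elif d == 2:
                (ax, ay), (bx, by) = dirs
                collinear = abs(ax * by - ay * bx) < 1e-9
                if not collinear:
                    counts["intersection_2way"] += 1
            elif d == 3:
                counts["intersection_3way"] += 1
            else:
                counts["intersection_4way"] += 1
        # mirror symmetry about the vertical axis: reflect segment endpoints
        reflected = {
            frozenset(((1.0 - a[0], a[1]), (1.0 - b[0], b[1]))) for a, b in pts
        }
        original = {frozenset((a, b)) for a, b in pts}
        counts["symmetry"] = int(reflected == original)
        # enclosed regions: independent cycles of the segment graph
        nodes = set(degree)
        comps = _n_components(nodes, pts)
        counts["closed_space"] = max(0, len(pts) - len(nodes) + comps)
        rows.append(dict(letter=letter, **counts))
    return pd.DataFrame(rows)


def _n_components(nodes, edges) -> int:
    parent = {n: n for n in nodes}

    def find(n):
        while parent[n] != n:
            parent[n] = parent[parent[n]]
            n = parent[n]
        return n

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(n) for n in nodes})


def _conv2d(x: np.ndarray, filters: np.ndarray) -> np.ndarray:
    """Valid 2-D convolution: (N, Cin, H, W) x (Cout, Cin, k, k)."""
    k = filters.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # win: (N, Cin, H-k+1, W-k+1, k, k)
    return np.einsum("ncxyij,ocij->noxy", win, filters)


def simulate_feature_hierarchy(
    glyphs: GlyphSet, n_stages: int, seed: int, n_features: int = 12
) -> list[ActivationSet]:
    """Untrained multi-stage feature hierarchy over the glyph images.

    Each stage applies a bank of random local filters, half-wave
    rectification (ReLU), and 2x downsampling; its maps are spatially
    summed into an :class:`~lettersim.models.ActivationSet`.  Purely a
    function of (glyphs, seed).
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    rng = np.random.default_rng(seed)
    imgs, letters, fonts = glyphs.flat()
    x = imgs[:, None, :, :]  # (N, 1, H, W)
    stages = []
    for s in range(n_stages):
        cin = x.shape[1]
        # fall back to 1x1 channel-mixing filters once maps are too small
        k = 3 if min(x.shape[2], x.shape[3]) >= 3 else 1
        filters = rng.normal(0.0, 1.0 / np.sqrt(cin * k * k),
                             size=(n_features, cin, k, k))
        fm = np.maximum(_conv2d(x, filters), 0.0)
        if fm.shape[-1] >= 4:  # 2x2 average-pool downsample
            h, w = fm.shape[2] - fm.shape[2] % 2, fm.shape[3] - fm.shape[3] % 2
            fm = fm[:, :, :h, :w].reshape(fm.shape[0], fm.shape[1], h // 2, 2, w // 2, 2)
            fm = fm.mean(axis=(3, 5))
        stages.append(
            pool_feature_maps(fm, stage=f"stage{s + 1}", letters=letters, fonts=fonts)
        )
        x = fm
    return stages
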