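import numpy as np
import pytest

from cbctseg.unetr_model import UNETR, UNETRConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def micro_config():
    """Smallest sensible network: 16-voxel window, 4-voxel patches."""
    return UNETRConfig(
        window_edge=16,
        patch_edge=4,
        hidden_dim=16,
        mlp_dim=32,
        num_heads=2,
        num_layers=2,
        skip_layers=(1, 2),
        feature_size=4,
        dropout_rate=0.0,
    )


@pytest.fixture(scope="session")
def micro_model(micro_config):
    return UNETR(micro_config, rng=np.random.default_rng(7))


class ConstantModel:
    """Stub predictor emitting a fixed class-probability pair everywhere."""

    def __init__(self, window_edge: int, p_fg: float = 0.3):
        self.window_edge = window_edge
        self.p_fg = p_fg

    def forward(self, batch):
        b, w = batch.shape[0], self.window_edge
        out = np.empty((b, 2, w, w, w), dtype=np.float32)
        out[:, 1] = self.p_fg
        out[:, 0] = 1.0 - self.p_fg
        return out


class OracleModel:
    """Stub predictor that thresholds the (normalized) image at 0.5.

    On noiseless phantoms whose label equals the bright region this is a
    perfect segmenter, which makes it an oracle for pipeline plumbing.
    """

    def __init__(self, window_edge: int, threshold: float = 0.5):
        self.window_edge = window_edge
        self.threshold = threshold

    def forward(self, batch):
        fg = (batch >= self.threshold).astype(np.float32)
        return np.stack([1.0 - fg, fg], axis=1)


@pytest.fixture
def constant_model_factory():
    return ConstantModel


@pytest.fixture
def oracle_model_factory():
    return OracleModel


# ---------------------------------------------------------------------
# independent brute-force oracles shared across test modules


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """BFS connected components of a binary 3-D mask."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                order = sum(map(abs, d))
                if (connectivity == 6 and order > 1) or (connectivity == 18 and order > 2):
                    continue
                offsets.append(d)
    todo = {tuple(i) for i in np.argwhere(mask)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if n in todo:
                    todo.remove(n)
                    comp.add(n)
                    frontier.append(n)
        comps.append(comp)
    return comps


def fill_holes_oracle(mask: np.ndarray) -> np.ndarray:
    """Flood-fill the background from the border (6-connected); the
    unreached background is interior cavity and becomes foreground."""
    bg = ~mask.astype(bool)
    reach = np.zeros_like(bg)
    frontier = [
        tuple(i)
        for i in np.argwhere(bg)
        if 0 in i or any(v == s - 1 for v, s in zip(i, bg.shape))
    ]
    for f in frontier:
        reach[f] = True
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while frontier:
        x, y, z = frontier.pop()
        for dx, dy, dz in offs:
            n = (x + dx, y + dy, z + dz)
            if all(0 <= v < s for v, s in zip(n, bg.shape)) and bg[n] and not reach[n]:
                reach[n] = True
                frontier.append(n)
    return mask.astype(bool) | (bg & ~reach)


def auprc_sweep_oracle(scores: np.ndarray, gt: np.ndarray) -> float:
    """Trapezoidal AUPRC over every unique threshold, by direct counting."""
    scores = scores.ravel()
    gt = gt.ravel().astype(bool)
    pts = []
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tp = int(np.count_nonzero(pred & gt))
        pts.append((tp / gt.sum(), tp / pred.sum()))
    pts = [(0.0, pts[0][1])] + pts
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p1 + p0) / 2.0
    return area
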