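import numpy as np
import pytest

from explantkit.types import CellOutline, ExplantMask, PixelCalibration


@pytest.fixture
def calib() -> PixelCalibration:
    return PixelCalibration(1.0, 1.0)


@pytest.fixture
def disk_mask() -> ExplantMask:
    """Rasterized disk, radius 100 px, 1 µm/px."""
    n = 220
    yy, xx = np.mgrid[:n, :n]
    mask = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= 100.0**2
    return ExplantMask(mask, PixelCalibration(1.0))


@pytest.fixture
def rect_mask() -> ExplantMask:
    """400x100 px rectangle, 1 µm/px."""
    mask = np.zeros((140, 440), bool)
    mask[20:120, 20:420] = True
    return ExplantMask(mask, PixelCalibration(1.0))


def ellipse_outline(
    a: float, b: float, angle_deg: float = 0.0,
    center=(0.0, 0.0), n: int = 64,
) -> CellOutline:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    xy = (rot @ np.stack([a * np.cos(t), b * np.sin(t)])).T + np.asarray(center)
    return CellOutline(xy)


def dijkstra_geodesic(mask: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Independent exact geodesic oracle: heap-based Dijkstra over the
    8-connected foreground grid with step weights 1 and sqrt(2)."""
    import heapq

    ny, nx = mask.shape
    dist = np.full((ny, nx), np.inf)
    heap = []
    for r, c in np.argwhere(sources & mask):
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, int(r), int(c)))
    steps = [
        (-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
        (-1, -1, 2**0.5), (-1, 1, 2**0.5), (1, -1, 2**0.5), (1, 1, 2**0.5),
    ]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc, w in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and mask[rr, cc]:
                nd = d + w
                if nd < dist[rr, cc]:
                    dist[rr, cc] = nd
                    heapq.heappush(heap, (nd, rr, cc))
    out = np.where(mask, dist, np.inf)
    return out
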