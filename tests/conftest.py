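from collections import deque

import numpy as np
import pytest

from omsbseg import SectionSpec, generate_section, segment_section


def draw_annulus(shape, center, r_in, r_out):
    """Rasterized annulus: pixels with r_in <= dist <= r_out (pixel centers)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return (dist >= r_in) & (dist <= r_out)


def bfs_components(mask, connectivity=8):
    """Exhaustive BFS connected-component labeling (test oracle)."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = r + dr, c + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels, current


def bfs_fill_interior(component):
    """Flood-fill oracle: interior = pixels 4-unreachable from the border
    through the background of `component`."""
    component = np.asarray(component, bool)
    h, w = component.shape
    outside = np.zeros((h, w), dtype=bool)
    queue = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not component[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not component[r, c] and not outside[r, c]:
                outside[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and not component[nr, nc] and not outside[nr, nc]:
                outside[nr, nc] = True
                queue.append((nr, nc))
    return ~component & ~outside


@pytest.fixture(scope="session")
def clean_section():
    """One noise-free synthetic section with its ground truth."""
    image, truth = generate_section(SectionSpec(seed=11))
    return image, truth


@pytest.fixture(scope="session")
def clean_segmentation(clean_section):
    image, truth = clean_section
    return segment_section(image), truth
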