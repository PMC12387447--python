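import numpy as np
import pytest

from citruslines import phantom


@pytest.fixture(scope="session")
def cam():
    return phantom.default_camera()


@pytest.fixture(scope="session")
def clean_spec():
    """Small, noiseless, artifact-free phantom for geometric oracles."""
    return phantom.PhantomSpec(seed=7, noise_sigma=0.0, artifact_rate=0.0,
                               n_frames=24)


@pytest.fixture(scope="session")
def clean_phantom(clean_spec, cam):
    field, truth = phantom.make_phantom_surface(clean_spec, cam)
    return field, truth


@pytest.fixture(scope="session")
def clean_frames(clean_spec, cam, clean_phantom):
    field, _ = clean_phantom
    return phantom.render_stripe_frames(field, cam, clean_spec)


def tree_longest_path_length(mask: np.ndarray) -> int:
    """Brute-force longest endpoint-to-endpoint pixel count on an 8-connected
    skeleton, via exhaustive simple-path search from every endpoint."""
    pts = list(zip(*np.nonzero(mask)))
    pset = set(pts)
    adj = {p: [(p[0] + dr, p[1] + dc)
               for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0) and (p[0] + dr, p[1] + dc) in pset]
           for p in pts}
    endpoints = [p for p in pts if len(adj[p]) == 1]
    best = 0

    def dfs(node, visited):
        nonlocal best
        if node in endpoints and len(visited) > 1:
            best = max(best, len(visited))
            return
        for nxt in adj[node]:
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, visited)
                visited.discard(nxt)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        for e in endpoints:
            dfs(e, {e})
    finally:
        sys.setrecursionlimit(old)
    return best
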