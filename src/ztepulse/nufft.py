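"""Kaiser-Bessel gridding NUFFT for 3D non-Cartesian reconstruction.

Type-2 forward (Cartesian image -> arbitrary k-space points) via
deapodization, zero-padded FFT on a 2x oversampled grid and separable
Kaiser-Bessel interpolation; the adjoint is the exact conjugate transpose of
the forward (scatter with the same kernel weights, inverse FFT, crop,
deapodize), so <Ax, y> == <x, A^H y> holds to machine precision by
construction.  Conventions match :mod:`ztepulse.geometry`: k in cycles/FOV,
voxel j at (j - n/2)/n, kernel exp(-2*pi*i k.x).

The forward model is calibrated against a centered unit impulse (whose exact
non-uniform DFT is 1 at every k) to remove the kernel-dependent global
scale.
"""

from __future__ import annotations

import numpy as np


def _kb_kernel(t: np.ndarray, width: float, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel, support |t| <= width/2 grid units."""
    z = 1.0 - (2.0 * t / width) ** 2
    out = np.where(z > 0, np.i0(beta * np.sqrt(np.maximum(z, 0.0))), 0.0)
    return out / np.i0(beta)


def _kb_ft(nu: np.ndarray, width: float, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the KB kernel at frequency nu (1/grid unit)."""
    arg = beta * beta - (np.pi * width * nu) ** 2
    pos = arg > 0
    root = np.sqrt(np.abs(arg))
    out = np.where(pos, np.sinh(np.maximum(root, 1e-30)) / np.maximum(root, 1e-30),
                   np.sinc(root / np.pi))
    return out * width / np.i0(beta)


class Nufft3:
    """3D gridding NUFFT operator for a fixed set of k-space sample points.

    Parameters
    ----------
    kpoints : (M, 3) array, cycles/FOV, all |k| components < matrix/2.
    n : base matrix size (isotropic).
    oversamp : grid oversampling factor (grid size = oversamp * n).
    width : kernel width in oversampled grid units.
    """

    def __init__(self, kpoints: np.ndarray, n: int, oversamp: float = 2.0,
                 width: int = 4):
        k = np.atleast_2d(np.asarray(kpoints, dtype=float))
        if k.shape[1] != 3:
            raise ValueError("kpoints must be (M, 3)")
        self.n = int(n)
        self.G = int(round(oversamp * n))
        if self.G % 2:
            self.G += 1
        os_eff = self.G / n
        self.width = width
        # Beatty et al. optimal shape parameter for this width/oversampling
        self.beta = np.pi * np.sqrt((width / os_eff * (os_eff - 0.5)) ** 2 - 0.8)
        self.M = k.shape[0]

        G, w = self.G, width
        gc = k * os_eff + G / 2.0                      # (M, 3) grid coords
        base = np.floor(gc - w / 2.0).astype(int) + 1  # first tap per axis
        offs = np.arange(w)
        idx_ax = base[:, :, None] + offs[None, None, :]          # (M, 3, w)
        wt_ax = _kb_kernel(idx_ax - gc[:, :, None], w, self.beta)
        idx_ax = np.mod(idx_ax, G)
        # combine separable axes into flat taps (M, w^3)
        ix, iy, iz = idx_ax[:, 0], idx_ax[:, 1], idx_ax[:, 2]
        wx, wy, wz = wt_ax[:, 0], wt_ax[:, 1], wt_ax[:, 2]
        flat = (ix[:, :, None, None] * G + iy[:, None, :, None]) * G \
            + iz[:, None, None, :]
        self._flat_idx = flat.reshape(self.M, -1)
        self._weights = (wx[:, :, None, None] * wy[:, None, :, None]
                         * wz[:, None, None, :]).reshape(self.M, -1)

        # deapodization over the central n-block
        j = (np.arange(n) - n / 2.0) / G
        c1 = _kb_ft(j, w, self.beta)
        self._deapod = c1[:, None, None] * c1[None, :, None] * c1[None, None, :]

        # calibrate global scale with a centered impulse (exact NUDFT == 1)
        self._scale = 1.0
        e = np.zeros((n, n, n))
        e[n // 2, n // 2, n // 2] = 1.0
        ref = self.forward(e)
        self._scale = 1.0 / float(np.mean(ref.real))

    # ------------------------------------------------------------------
    def _fft_pad(self, x: np.ndarray) -> np.ndarray:
        n, G = self.n, self.G
        pad = np.zeros((G, G, G), dtype=complex)
        a = (G - n) // 2
        pad[a:a + n, a:a + n, a:a + n] = x / self._deapod
        return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(pad)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        """A x: evaluate the image's transform at the sample points, (M,)."""
        X = self._fft_pad(np.asarray(x, dtype=complex)).ravel()
        y = np.sum(X[self._flat_idx] * self._weights, axis=1)
        return y * self._scale

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """A^H y: exact conjugate-transpose of :meth:`forward`, (n, n, n)."""
        n, G = self.n, self.G
        contrib = (np.asarray(y, dtype=complex)[:, None] * self._weights).ravel()
        idx = self._flat_idx.ravel()
        grid = (np.bincount(idx, weights=contrib.real, minlength=G ** 3)
                + 1j * np.bincount(idx, weights=contrib.imag, minlength=G ** 3))
        grid = grid.reshape(G, G, G)
        xpad = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * G ** 3
        a = (G - n) // 2
        x = xpad[a:a + n, a:a + n, a:a + n] / self._deapod
        return x * self._scale
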