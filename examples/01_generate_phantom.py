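"""Generate a periodic linear-gradient phantom and inspect its structure.

The phantom is the idealized image the closed-form GLCM theory assumes:
a vertical intensity ramp climbing `grad` levels per pixel that restarts
at zero after one period, replicated across all columns.
"""

from gradtex import GradientSpec, make_gradient_image, n_tilde

spec = GradientSpec(ng=8, grad=2, width=6, height=12)
img = make_gradient_image(spec)

print(f"gray levels     : {spec.ng}")
print(f"gradient        : {spec.grad} levels/pixel")
print(f"period          : {n_tilde(spec.ng, spec.grad)} pixels "
      "(= number of distinct levels the ramp visits)")
print("first column    :", img.pixels[:, 0].tolist())
print("image rows are constant-intensity stripes; the pattern repeats "
      "every period rows.")

# exact-period trimming guarantees uniform GLCM counts at displacement 1
trimmed = make_gradient_image(
    GradientSpec(ng=8, grad=2, width=6, height=12, exact_period_for=1)
)
print(f"exact-period height for |d|=1: {trimmed.height} "
      "(height - 1 is a multiple of the period)")
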