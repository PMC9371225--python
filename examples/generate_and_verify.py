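"""Zero-watermark a synthetic phantom and verify it, clean and attacked.

Builds a 256x256 brain-like phantom and a 32x32 checkerboard watermark,
registers the zero-watermark (the carrier is never modified), then verifies
on the untouched carrier and on a JPEG-recompressed copy.  BER is the
fraction of wrong bits in the extracted watermark (0 = perfect); NC is its
normalized correlation with the original (1 = perfect); PSNR quantifies how
much the attack distorted the carrier.
"""

import zeromark as zm

spec = zm.BasisSpec(grid_n=256)
carrier = zm.make_phantom(zm.PhantomSpec(side=256, seed=1))
w = zm.make_watermark("checkerboard", 32, 32)
sel_key = zm.SelectionKey(42)
scr_key = zm.ChebyshevKey(r=4.0, x0=0.631)

zero_wm = zm.generate(carrier, w, sel_key, scr_key, spec)
clean = zm.verify(carrier, zero_wm, sel_key, scr_key, spec, reference=w)
print(f"clean carrier:  BER = {clean.ber:.4f}  NC = {clean.nc:.4f}")

attack = zm.AttackSpec("jpeg", {"quality": 70})
attacked = zm.apply_attack(carrier, attack)
res = zm.verify(attacked, zero_wm, sel_key, scr_key, spec, reference=w)
print(
    f"{attack.label()}: BER = {res.ber:.4f}  NC = {res.nc:.4f}  "
    f"PSNR = {zm.psnr(carrier, attacked):.2f} dB"
)
print("BER 0 / NC 1 on the clean carrier is exact recovery; small BER after")
print("the attack means the moment features largely survived recompression.")
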