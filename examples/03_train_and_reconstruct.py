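"""Train a small Partial-CNN and reconstruct a partial acquisition.

A deliberately tiny run (60 scenes, 64x64, a few epochs) so the script
finishes in about a minute; the package's full desk-scale study lives in
scripts/acceptance.py.  Prints the PSNR/SSIM of the trained model
against the linear-interpolation baseline on two held-out scenes.  At
this toy scale the model only roughly matches the baseline — the
desk-scale study trains long enough to surpass it.
"""

import partialscan as ps

scenes = [ps.normalize(h) for h in
          ps.generate_dataset(62, ps.SceneParams(image_size=(64, 64)), seed=5)]
train_pool, test = scenes[:60], scenes[60:]

cfg = ps.ModelConfig(arch="partial_cnn", filters=(8, 16), input_size=(64, 64))
tc = ps.TrainConfig(folds=2, max_epochs=8, patience=4, crop_size=None, seed=0)
model = ps.train(ps.build_model(cfg, seed=1), train_pool, tc=tc,
                 lc=ps.LossConfig())
print(f"trained partial_cnn, {model.n_parameters} parameters, "
      f"{len(model.training_history)} epoch records")

for i, img in enumerate(test):
    lm = ps.random_line_mask(img.n_rows, 0.30, seed=100 + i)
    partial, raster = ps.acquire_partial(img, lm)
    recon = ps.reconstruct(model, partial, raster)
    interp = ps.interpolate_linear(partial, raster)
    print(f"scene {i}: partial_cnn PSNR {ps.psnr(img, recon):.2f} dB / "
          f"SSIM {ps.ssim(img, recon):.4f}   "
          f"interp PSNR {ps.psnr(img, interp):.2f} dB / "
          f"SSIM {ps.ssim(img, interp):.4f}")
print("scanned rows are copied verbatim; only skipped lines carry model output")
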