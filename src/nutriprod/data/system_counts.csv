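terrestrial,aquatic,count
none,F,184
none,FP,32
none,FPS,135
none,FS,52
rice,F,16
rice,FP,33
rice,FPS,29
rice,FS,8
vf,F,68
vf,FP,31
vf,FPS,12
vf,FS,1
rice_vf,F,16
rice_vf,FP,69
rice_vf,FPS,35
rice_vf,FS,0
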