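trait,treatment,min,max,mean,sd,cv_percent
plant_height,control,20.10,47.80,35.82,4.95,13.82
stem_diameter,control,1.08,2.59,1.81,0.30,16.57
spad,control,14.70,43.50,30.19,6.98,23.12
leaf_thickness,control,0.21,0.87,0.52,0.11,21.15
afw,control,0.18,1.15,0.54,0.21,38.89
adw,control,0.02,0.15,0.07,0.03,42.86
pn,control,2.55,13.55,6.98,2.63,37.68
proline,control,68.39,975.78,422.41,266.55,63.10
rubisco,control,64.30,411.52,210.43,69.05,32.81
plant_height,stress,17.00,44.00,31.51,5.29,16.79
stem_diameter,stress,0.58,2.61,1.55,0.40,25.81
spad,stress,5.00,42.20,24.37,9.09,37.30
leaf_thickness,stress,0.15,0.74,0.46,0.14,30.43
afw,stress,0.07,0.96,0.42,0.20,47.62
adw,stress,0.01,0.14,0.06,0.03,50.00
pn,stress,0.84,10.19,4.13,2.37,57.38
proline,stress,102.18,1357.09,571.95,328.76,57.48
rubisco,stress,25.72,334.36,168.22,66.95,39.80
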