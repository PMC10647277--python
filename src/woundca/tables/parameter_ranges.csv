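parameter,description,low,high,unit,kind
tm,Characteristic time of migration,0.005,0.5,h,input
td,Characteristic time of proliferation,12,40,h,input
rho,Density: number of cells in unit area,1e-6,1e-3,cells/um^2,input
delta,Characteristic dimension of the cell,15,25,um,input
b0,Initial length of the wound,370,900,um,input
D,Motility: the time necessary to travel a length equal to delta,1e3,1e4,um^2/h,output
v,Velocity of the fronts of cells,5,60,um/h,output
alpha,Velocity of wound area variation,0.02,0.13,1/h,output
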