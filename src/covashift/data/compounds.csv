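id,code,formula,leaving_group_formula,warhead_class
12,5ax,C10H9F4NO6S2,C2H4O2,ester
,5bx,C11H11F4NO6S2,C2H4O2,ester
,5cx,C11H11F4NO6S2,,none
,5dx,C11H11F4NO6S2,C3H6O2,ester
,5ex,C13H15F4NO6S2,C5H10O2,ester
,5fx,C16H13F4NO6S2,C8H8O2,ester
,7x,C10H9F4NO6S2,,none
,8x,C10H9F4NO4S2,,none
,10x,C10H9F4NO5S2,,none
15,11x,C8H5F4NO4S2,,vinylsulfone
,14x,C12H13F4NO6S2,,none
,16x,C11H12F4N2O5S2,,none
,24ax,C15H12F4N2O6S2,C7H7NO2,carbamate
,24bx,C16H14F4N2O7S2,C8H9NO3,carbamate
,27ax,C18H25F3N2O6S2,C2H4O2,ester
,27bx,C22H33F3N2O6S2,C2H4O2,ester
,28ax,C19H27F3N2O6S2,C3H6O2,ester
,28bx,C23H35F3N2O6S2,C3H6O2,ester
22,30x,C23H28F3N3O6S2,C7H7NO2,carbamate
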