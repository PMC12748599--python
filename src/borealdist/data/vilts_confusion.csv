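map_class,no_change,wildfire,harvesting,windthrow,pest_harv,pest
no_change,531,8,31,9,2,95
wildfire,0,116,0,0,0,2
harvesting,3,0,96,3,6,3
windthrow,1,3,4,10,0,6
pest_harv,0,2,3,0,18,0
pest,7,10,5,0,1,96
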