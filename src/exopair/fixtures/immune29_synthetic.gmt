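aDCs	synthetic_placeholder_members	SIG00G00	SIG00G01	SIG00G02	SIG00G03	SIG00G04	SIG00G05	SIG00G06	SIG00G07	SIG00G08	SIG00G09
APC_co_inhibition	synthetic_placeholder_members	SIG01G00	SIG01G01	SIG01G02	SIG01G03	SIG01G04	SIG01G05	SIG01G06	SIG01G07	SIG01G08	SIG01G09
APC_co_stimulation	synthetic_placeholder_members	SIG02G00	SIG02G01	SIG02G02	SIG02G03	SIG02G04	SIG02G05	SIG02G06	SIG02G07	SIG02G08	SIG02G09
B_cells	synthetic_placeholder_members	SIG03G00	SIG03G01	SIG03G02	SIG03G03	SIG03G04	SIG03G05	SIG03G06	SIG03G07	SIG03G08	SIG03G09
CCR	synthetic_placeholder_members	SIG04G00	SIG04G01	SIG04G02	SIG04G03	SIG04G04	SIG04G05	SIG04G06	SIG04G07	SIG04G08	SIG04G09
CD8_T_cells	synthetic_placeholder_members	SIG05G00	SIG05G01	SIG05G02	SIG05G03	SIG05G04	SIG05G05	SIG05G06	SIG05G07	SIG05G08	SIG05G09
Check_point	synthetic_placeholder_members	SIG06G00	SIG06G01	SIG06G02	SIG06G03	SIG06G04	SIG06G05	SIG06G06	SIG06G07	SIG06G08	SIG06G09
Cytolytic_activity	synthetic_placeholder_members	SIG07G00	SIG07G01	SIG07G02	SIG07G03	SIG07G04	SIG07G05	SIG07G06	SIG07G07	SIG07G08	SIG07G09
DCs	synthetic_placeholder_members	SIG08G00	SIG08G01	SIG08G02	SIG08G03	SIG08G04	SIG08G05	SIG08G06	SIG08G07	SIG08G08	SIG08G09
HLA	synthetic_placeholder_members	SIG09G00	SIG09G01	SIG09G02	SIG09G03	SIG09G04	SIG09G05	SIG09G06	SIG09G07	SIG09G08	SIG09G09
iDCs	synthetic_placeholder_members	SIG10G00	SIG10G01	SIG10G02	SIG10G03	SIG10G04	SIG10G05	SIG10G06	SIG10G07	SIG10G08	SIG10G09
Inflammation_promoting	synthetic_placeholder_members	SIG11G00	SIG11G01	SIG11G02	SIG11G03	SIG11G04	SIG11G05	SIG11G06	SIG11G07	SIG11G08	SIG11G09
Macrophages	synthetic_placeholder_members	SIG12G00	SIG12G01	SIG12G02	SIG12G03	SIG12G04	SIG12G05	SIG12G06	SIG12G07	SIG12G08	SIG12G09
Mast_cells	synthetic_placeholder_members	SIG13G00	SIG13G01	SIG13G02	SIG13G03	SIG13G04	SIG13G05	SIG13G06	SIG13G07	SIG13G08	SIG13G09
MHC_class_I	synthetic_placeholder_members	SIG14G00	SIG14G01	SIG14G02	SIG14G03	SIG14G04	SIG14G05	SIG14G06	SIG14G07	SIG14G08	SIG14G09
Neutrophils	synthetic_placeholder_members	SIG15G00	SIG15G01	SIG15G02	SIG15G03	SIG15G04	SIG15G05	SIG15G06	SIG15G07	SIG15G08	SIG15G09
NK_cells	synthetic_placeholder_members	SIG16G00	SIG16G01	SIG16G02	SIG16G03	SIG16G04	SIG16G05	SIG16G06	SIG16G07	SIG16G08	SIG16G09
Parainflammation	synthetic_placeholder_members	SIG17G00	SIG17G01	SIG17G02	SIG17G03	SIG17G04	SIG17G05	SIG17G06	SIG17G07	SIG17G08	SIG17G09
pDCs	synthetic_placeholder_members	SIG18G00	SIG18G01	SIG18G02	SIG18G03	SIG18G04	SIG18G05	SIG18G06	SIG18G07	SIG18G08	SIG18G09
T_cell_co_inhibition	synthetic_placeholder_members	SIG19G00	SIG19G01	SIG19G02	SIG19G03	SIG19G04	SIG19G05	SIG19G06	SIG19G07	SIG19G08	SIG19G09
T_cell_co_stimulation	synthetic_placeholder_members	SIG20G00	SIG20G01	SIG20G02	SIG20G03	SIG20G04	SIG20G05	SIG20G06	SIG20G07	SIG20G08	SIG20G09
T_helper_cells	synthetic_placeholder_members	SIG21G00	SIG21G01	SIG21G02	SIG21G03	SIG21G04	SIG21G05	SIG21G06	SIG21G07	SIG21G08	SIG21G09
Tfh	synthetic_placeholder_members	SIG22G00	SIG22G01	SIG22G02	SIG22G03	SIG22G04	SIG22G05	SIG22G06	SIG22G07	SIG22G08	SIG22G09
Th1_cells	synthetic_placeholder_members	SIG23G00	SIG23G01	SIG23G02	SIG23G03	SIG23G04	SIG23G05	SIG23G06	SIG23G07	SIG23G08	SIG23G09
Th2_cells	synthetic_placeholder_members	SIG24G00	SIG24G01	SIG24G02	SIG24G03	SIG24G04	SIG24G05	SIG24G06	SIG24G07	SIG24G08	SIG24G09
TIL	synthetic_placeholder_members	SIG25G00	SIG25G01	SIG25G02	SIG25G03	SIG25G04	SIG25G05	SIG25G06	SIG25G07	SIG25G08	SIG25G09
Treg	synthetic_placeholder_members	SIG26G00	SIG26G01	SIG26G02	SIG26G03	SIG26G04	SIG26G05	SIG26G06	SIG26G07	SIG26G08	SIG26G09
Type_I_IFN_response	synthetic_placeholder_members	SIG27G00	SIG27G01	SIG27G02	SIG27G03	SIG27G04	SIG27G05	SIG27G06	SIG27G07	SIG27G08	SIG27G09
Type_II_IFN_response	synthetic_placeholder_members	SIG28G00	SIG28G01	SIG28G02	SIG28G03	SIG28G04	SIG28G05	SIG28G06	SIG28G07	SIG28G08	SIG28G09
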